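"""Monoisotopic mass arithmetic for photo-methionine cross-linking chemistry.

Photo-methionine (pMet, L-2-amino-5,5-azi-hexanoic acid) replaces the
thioether sulfur of methionine with a diazirine ring.  UV photolysis expels
N2 and leaves a carbene that either inserts into a nearby bond (forming a
zero-length cross-link or a solvent adduct) or collapses to an alkene
"termination product".  In every photolysed outcome the residue is lighter
than natural methionine by the sulfur-for-carbon swap:

    delta = mass(C5H9NOS) - mass(C6H9NO) = mass(S) - mass(C) = 19.9721 u

All constants here are derived at runtime from elemental monoisotopic
masses (pyteomics' NIST table), so the 19.972 shift is a computed quantity,
never a hard-coded literal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence, Tuple

from pyteomics import mass as _pmass

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Modification:
    """A fixed-delta covalent modification.

    target is a one-letter residue code, or '*' when the modification applies
    to the whole molecule (e.g. H -> Na exchange).  stackable_on names the
    modification state this one applies on top of (adducts only exist on a
    photolysed pMet site).
    """

    id: str
    target: str
    delta_mass: float
    stackable_on: str | None = None


class ChemicalContext:
    """Element and residue monoisotopic masses plus the pMet modification registry.

    Attributes
    ----------
    element_masses : dict
        element symbol -> monoisotopic mass (u).
    residue_masses : dict
        one-letter amino-acid code -> residue (internal) monoisotopic mass (u).
    proton_mass, water_mass : float
        in u; protonation uses the proton mass (1.007276 u), not the
        hydrogen-atom mass -- the convention that reproduces the published
        [M+H]+ values to <0.1 ppm.
    modifications : dict
        modification id -> :class:`Modification`.
    """

    def __init__(self) -> None:
        nist = _pmass.nist_mass
        self.element_masses = {
            el: data[0][0] for el, data in nist.items() if 0 in data and el != "H+"
        }
        self.proton_mass = nist["H+"][0][0]
        self.residue_masses = {
            aa: self.formula_mass(dict(comp))
            for aa, comp in _pmass.std_aa_comp.items()
            if len(aa) == 1 and aa.isupper()
        }
        self.water_mass = self.formula_mass("H2O")
        self.modifications = self._build_registry()

    # -- formulas ---------------------------------------------------------

    def formula_mass(self, formula: str | Mapping[str, int]) -> float:
        """Monoisotopic mass of an elemental formula ('C6H9NO' or a dict)."""
        if isinstance(formula, str):
            counts: dict[str, int] = {}
            pos = 0
            for m in _FORMULA_TOKEN.finditer(formula):
                if m.start() != pos:
                    raise ValueError(f"cannot parse formula {formula!r}")
                pos = m.end()
                counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            if pos != len(formula):
                raise ValueError(f"cannot parse formula {formula!r}")
        else:
            counts = dict(formula)
        try:
            return sum(self.element_masses[el] * n for el, n in counts.items())
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"unknown element {exc}") from exc

    def _build_registry(self) -> dict[str, Modification]:
        met = self.formula_mass("C5H9NOS")  # natural Met residue
        alkene = self.formula_mass("C6H9NO")  # termination product residue
        diazirine = self.formula_mass("C6H9N3O")  # intact photo-Met residue
        mods = [
            # intact diazirine analog; excluded from default searches because
            # the MALDI laser photolyses it in-source
            Modification("pmet_intact", "M", diazirine - met),
            # photolysed, no partner: alkene termination product
            Modification("pmet_terminated", "M", alkene - met),
            # photolysed, carbene inserted into a partner bond; the partner
            # mass is accounted for separately by the cross-link species
            Modification("pmet_inserted", "M", alkene - met),
            # carbamidomethyl on Cys (iodoacetamide)
            Modification("cam", "C", self.formula_mass("C2H3NO")),
            # whole glycerol molecule captured by carbene insertion
            Modification(
                "glycerol_adduct",
                "M",
                self.formula_mass("C3H8O3"),
                stackable_on="pmet_inserted",
            ),
            # one proton-bearing H exchanged for Na
            Modification(
                "sodiated",
                "*",
                self.element_masses["Na"] - self.element_masses["H"],
                stackable_on="glycerol_adduct",
            ),
        ]
        return {m.id: m for m in mods}

    @property
    def pmet_termination_shift(self) -> float:
        """The mass lost by a photolysed pMet relative to natural Met (+19.9721 u)."""
        return -self.modifications["pmet_terminated"].delta_mass

    # -- peptides ---------------------------------------------------------

    def peptide_neutral_mass(
        self,
        sequence: str,
        mods: Iterable[Tuple[int, Modification]] = (),
    ) -> float:
        """Neutral monoisotopic mass of a peptide with site modifications.

        Parameters
        ----------
        sequence : str
            Residue string in one-letter code.
        mods : iterable of (position, Modification)
            1-based positions within the peptide; position 0 targets the
            molecule as a whole (for '*' modifications such as Na exchange).
        """
        if not sequence:
            raise ValueError("empty peptide sequence")
        try:
            total = sum(self.residue_masses[aa] for aa in sequence)
        except KeyError as exc:
            raise ValueError(f"unknown residue code {exc} in {sequence!r}") from exc
        total += self.water_mass
        for pos, mod in mods:
            if mod.target == "*":
                total += mod.delta_mass
                continue
            if not 1 <= pos <= len(sequence):
                raise ValueError(f"modification position {pos} outside {sequence!r}")
            if sequence[pos - 1] != mod.target:
                raise ValueError(
                    f"modification {mod.id} targets {mod.target}, "
                    f"but residue {pos} of {sequence!r} is {sequence[pos - 1]}"
                )
            total += mod.delta_mass
        return total

    def mz_singly_protonated(self, neutral_mass: float) -> float:
        """[M+H]+ m/z of a neutral species (all published data are 1+)."""
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return neutral_mass + self.proton_mass

    @staticmethod
    def ppm_error(observed: float, theoretical: float) -> float:
        """Signed relative error, parts per million."""
        if observed <= 0 or theoretical <= 0:
            raise ValueError("m/z values must be positive")
        return 1e6 * (observed - theoretical) / theoretical


@lru_cache(maxsize=1)
def default_context() -> ChemicalContext:
    """Shared immutable-in-practice ChemicalContext."""
    return ChemicalContext()
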