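"""Theoretical database of photo-cross-linked and photolysis-modified species.

Every identifiable species is built from tryptic peptides and the single
mass rule of diazirine photo-chemistry: each photolysed pMet site costs the
termination shift (19.9721 u) whether the carbene terminated, looped back
into its own peptide, inserted into a partner peptide (interlink) or into a
solvent molecule (adduct).  Hence

    interlink  = mass(peptide_a) + mass(peptide_b) - 19.9721
    monolink   = mass(peptide)   - k * 19.9721        (k photolysed sites)
    looplink   = same mass as the monolink (isobaric twin)
    adduct     = monolink + adduct mass (e.g. glycerol +92.0473, +Na +21.9819)

Positional alternatives (which of several Met residues is photolysed) are
mass-identical and collapse into one species carrying all placements;
MS/MS localization resolves them.  Interlinks between two Met-bearing
peptides instead yield one entry per choice of reactive chain -- same mass,
distinct identities -- reproducing the dual interpretation of the m/z 1998
signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chem import ChemicalContext, Modification, default_context
from .digestion import Peptide, met_sites

KINDS = (
    "interlink",
    "monolink_terminated",
    "looplink",
    "adducted_monolink",
    "monolink_intact",
)


def peptide_base_mass(peptide: Peptide, ctx: ChemicalContext) -> float:
    """Neutral mass of a peptide with its parent's fixed modifications applied."""
    mods = []
    for mod_id in peptide.parent.fixed_mods:
        mod = ctx.modifications[mod_id]
        for i, aa in enumerate(peptide.sequence):
            if aa == mod.target:
                mods.append((i + 1, mod))
    return ctx.peptide_neutral_mass(peptide.sequence, mods)


@dataclass(frozen=True)
class CrosslinkSpecies:
    """A candidate identifiable species with theoretical neutral mass.

    placements lists the alternative photolysed-site assignments (tuples of
    parent-numbering Met indices); for an interlink there is exactly one
    placement of one site, exposed as :attr:`pmet_site`.  peptide_a is the
    pMet-carrying chain; peptide_b the partner (interlinks only).
    partner_site stays None until MS/MS localization.
    """

    id: str
    kind: str
    peptide_a: Peptide
    peptide_b: Optional[Peptide]
    placements: Tuple[Tuple[int, ...], ...]
    neutral_mass: float
    extra_mods: Tuple[str, ...] = ()
    partner_site: Optional[int] = None
    isobaric_with: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown species kind {self.kind!r}")
        if self.kind == "interlink":
            if self.peptide_b is None:
                raise ValueError("interlink requires a partner peptide")
            if not met_sites(self.peptide_a):
                raise ValueError("interlink carrier has no Met")

    @property
    def pmet_site(self) -> int:
        return self.placements[0][0]

    @property
    def n_photolysed(self) -> int:
        return len(self.placements[0])

    def mz(self, ctx: ChemicalContext | None = None) -> float:
        ctx = ctx or default_context()
        return ctx.mz_singly_protonated(self.neutral_mass)


def enumerate_interlinks(
    peptides: Sequence[Peptide], ctx: ChemicalContext | None = None
) -> List[CrosslinkSpecies]:
    """One species per (Met-bearing carrier, partner peptide, Met site).

    Unordered peptide pairs are considered once; a pair of two Met-bearing
    peptides produces one entry per choice of reactive chain.  Homotypic
    pairs (a peptide cross-linked to another copy of itself) are legal in a
    homodimer and are included.
    """
    ctx = ctx or default_context()
    shift = ctx.pmet_termination_shift
    masses = [peptide_base_mass(p, ctx) for p in peptides]
    species = []
    for i, p in enumerate(peptides):
        for j in range(i, len(peptides)):
            q = peptides[j]
            pair_mass = masses[i] + masses[j] - shift
            roles = [(p, q)] if i == j else [(p, q), (q, p)]
            for carrier, partner in roles:
                for site in met_sites(carrier):
                    species.append(
                        CrosslinkSpecies(
                            id=f"IL:{carrier.coords}|{partner.coords}|pM{site}",
                            kind="interlink",
                            peptide_a=carrier,
                            peptide_b=partner,
                            placements=((site,),),
                            neutral_mass=pair_mass,
                        )
                    )
    return species


def _adduct_stacks(adducts: Sequence[Modification]) -> List[Tuple[Modification, ...]]:
    """Expand an adduct list into the modification stacks they form.

    A base adduct sits directly on a photolysed pMet (stackable_on a pmet
    state); further adducts stack on a base adduct (e.g. Na exchange on the
    glycerol adduct).
    """
    bases = [a for a in adducts if a.stackable_on in ("pmet_inserted", "pmet_terminated")]
    extras = [a for a in adducts if a not in bases]
    stacks: List[Tuple[Modification, ...]] = []
    for base in bases:
        stack = (base,)
        stacks.append(stack)
        for extra in extras:
            if extra.stackable_on == base.id:
                stacks.append(stack + (extra,))
    return stacks


def enumerate_monolinks(
    peptides: Sequence[Peptide],
    adducts: Sequence[Modification] = (),
    ctx: ChemicalContext | None = None,
) -> List[CrosslinkSpecies]:
    """Dead-end, loop-link and adducted species for every Met-bearing peptide.

    For k photolysed sites out of n Mets a single mass species is produced
    with all n-choose-k placements attached; its loop-link twin (isobaric by
    construction) is emitted whenever the peptide offers a partner residue
    besides the pMet site, and each adduct stack yields an adducted variant.
    """
    ctx = ctx or default_context()
    shift = ctx.pmet_termination_shift
    stacks = _adduct_stacks(adducts)
    species = []
    for pep in peptides:
        sites = met_sites(pep)
        if not sites:
            continue
        m0 = peptide_base_mass(pep, ctx)
        for k in range(1, len(sites) + 1):
            placements = tuple(itertools.combinations(sites, k))
            mass_k = m0 - k * shift
            ml_id = f"ML:{pep.coords}|k{k}"
            ll_id = f"LL:{pep.coords}|k{k}"
            has_loop_partner = len(pep) >= 2 + 1  # >=2 residues besides the pMet
            species.append(
                CrosslinkSpecies(
                    id=ml_id,
                    kind="monolink_terminated",
                    peptide_a=pep,
                    peptide_b=None,
                    placements=placements,
                    neutral_mass=mass_k,
                    isobaric_with=(ll_id,) if has_loop_partner else (),
                )
            )
            if has_loop_partner:
                species.append(
                    CrosslinkSpecies(
                        id=ll_id,
                        kind="looplink",
                        peptide_a=pep,
                        peptide_b=None,
                        placements=placements,
                        neutral_mass=mass_k,
                        isobaric_with=(ml_id,),
                    )
                )
            for stack in stacks:
                mod_ids = tuple(m.id for m in stack)
                species.append(
                    CrosslinkSpecies(
                        id=f"AD:{pep.coords}|k{k}|{'+'.join(mod_ids)}",
                        kind="adducted_monolink",
                        peptide_a=pep,
                        peptide_b=None,
                        placements=placements,
                        neutral_mass=mass_k + sum(m.delta_mass for m in stack),
                        extra_mods=mod_ids,
                    )
                )
    return species


class SpeciesDatabase:
    """Mass-sorted index over candidate species supporting ppm range queries."""

    def __init__(self, species: Iterable[CrosslinkSpecies],
                 ctx: ChemicalContext | None = None) -> None:
        self.ctx = ctx or default_context()
        self.species = sorted(species, key=lambda s: s.neutral_mass)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")
        self.by_id = {s.id: s for s in self.species}
        self._masses = np.array([s.neutral_mass for s in self.species])

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def query_neutral(self, mass: float, tol_ppm: float) -> List[CrosslinkSpecies]:
        """Species whose neutral mass lies within tol_ppm of the query mass."""
        if tol_ppm <= 0:
            raise ValueError("tolerance must be positive")
        lo = mass / (1 + tol_ppm * 1e-6)
        hi = mass / (1 - tol_ppm * 1e-6)
        i = np.searchsorted(self._masses, lo, side="left")
        j = np.searchsorted(self._masses, hi, side="right")
        return self.species[i:j]

    def query_mz(self, mz: float, tol_ppm: float) -> List[CrosslinkSpecies]:
        """Species whose theoretical [M+H]+ lies within tol_ppm of an observed m/z."""
        proton = self.ctx.proton_mass
        if tol_ppm <= 0:
            raise ValueError("tolerance must be positive")
        lo = mz / (1 + tol_ppm * 1e-6) - proton
        hi = mz / (1 - tol_ppm * 1e-6) - proton
        i = np.searchsorted(self._masses, lo, side="left")
        j = np.searchsorted(self._masses, hi, side="right")
        return self.species[i:j]


def build_database(
    species: Iterable[CrosslinkSpecies], ctx: ChemicalContext | None = None
) -> SpeciesDatabase:
    """Index candidate species by neutral mass (stable ids, ppm range queries)."""
    return SpeciesDatabase(species, ctx)
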