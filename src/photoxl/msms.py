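"""Theoretical fragment ions, spectrum annotation and cross-link site localization.

Fragmentation model (MALDI-TOF/TOF, singly charged):

* linear b/y series -- b_i is the sum of the first i residues (+ site
  modifications) plus a proton; y_i the last i residues plus water and a
  proton;
* for a cross-linked pair, any fragment of one chain that contains the
  linked residue carries the entire partner chain (partner mass minus the
  19.9721 u termination shift);
* the cross-link covalent bond itself can break, releasing the carrier
  chain as its alkene termination product ("xl_cleavage_alkene") and the
  partner chain restored to its linear form ("xl_cleavage_restored") --
  the published 613/730-class ion pairs.

Nominal integer labels use floor(exact m/z), the convention of the
published spectra (y4 at 1214.69 is printed 1214).

Localization enumerates every (partner residue x pMet site) hypothesis,
keeps only site-determining fragments (those whose mass differs between at
least two live hypotheses) and scores matched support minus conflicts.  The
C-terminal K/R of a tryptic peptide is excluded as a candidate link site by
default: a cross-linked side chain there would have blocked the trypsin
cleavage that produced the observed peptide boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from pyteomics import mgf as _mgf

from .chem import ChemicalContext, Modification, default_context
from .digestion import Peptide
from .ms1_match import PeakList
from .xl_candidates import CrosslinkSpecies, peptide_base_mass

#: two theoretical masses closer than this are the same ion (u)
MASS_RESOLUTION = 1e-6

#: default MS/MS matching tolerance (u), integer-labeled TOF/TOF peaks
DEFAULT_TOL_MU = 0.5


@dataclass(frozen=True)
class FragmentIon:
    chain: str  # 'a' (pMet carrier / the peptide itself) or 'b' (partner)
    series: str  # b | y | xl_cleavage_alkene | xl_cleavage_restored
    index: Optional[int]  # ordinal within series; None for xl_cleavage ions
    carries_partner: bool
    exact_mz: float
    label: str

    @property
    def nominal_mz(self) -> int:
        return math.floor(self.exact_mz)


def _site_deltas(
    sequence: str, mods: Iterable[Tuple[int, Modification]]
) -> List[float]:
    """Per-residue modification deltas (1-based positions; '*' mods ignored:
    they live on the intact molecule, not on backbone fragments)."""
    deltas = [0.0] * len(sequence)
    for pos, mod in mods:
        if mod.target == "*":
            continue
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"mod position {pos} outside peptide")
        if sequence[pos - 1] != mod.target:
            raise ValueError(
                f"{mod.id} targets {mod.target}, residue {pos} is {sequence[pos - 1]}"
            )
        deltas[pos - 1] += mod.delta_mass
    return deltas


def fragments_linear(
    sequence: str,
    mods: Iterable[Tuple[int, Modification]] = (),
    ctx: ChemicalContext | None = None,
    chain: str = "a",
    attach: Optional[Tuple[int, float]] = None,
) -> List[FragmentIon]:
    """Full b and y series (1..n-1) of a peptide with site modifications.

    ``attach=(local_pos, mass)`` hangs an extra mass (a cross-linked partner
    chain) on one residue; fragments containing it are flagged
    carries_partner.
    """
    ctx = ctx or default_context()
    if len(sequence) < 2:
        raise ValueError("need at least 2 residues to fragment")
    deltas = _site_deltas(sequence, mods)
    attach_pos = attach[0] if attach else None
    if attach_pos is not None and not 1 <= attach_pos <= len(sequence):
        raise ValueError("attachment position outside peptide")
    res = [ctx.residue_masses[aa] + d for aa, d in zip(sequence, deltas)]
    n = len(sequence)
    out: List[FragmentIon] = []
    # prefix sums for b; suffix for y
    acc = 0.0
    for i in range(1, n):
        acc += res[i - 1]
        carries = attach_pos is not None and attach_pos <= i
        mz = acc + ctx.proton_mass + (attach[1] if carries else 0.0)
        out.append(
            FragmentIon(chain, "b", i, carries, mz,
                        f"{chain}:b{i}" + ("+P" if carries else ""))
        )
    acc = 0.0
    for i in range(1, n):
        acc += res[n - i]
        carries = attach_pos is not None and attach_pos > n - i
        mz = acc + ctx.water_mass + ctx.proton_mass + (attach[1] if carries else 0.0)
        out.append(
            FragmentIon(chain, "y", i, carries, mz,
                        f"{chain}:y{i}" + ("+P" if carries else ""))
        )
    return out


def _fixed_mods(peptide: Peptide, ctx: ChemicalContext) -> List[Tuple[int, Modification]]:
    mods = []
    for mod_id in peptide.parent.fixed_mods:
        mod = ctx.modifications[mod_id]
        for i, aa in enumerate(peptide.sequence):
            if aa == mod.target:
                mods.append((i + 1, mod))
    return mods


def fragments_peptide(
    peptide: Peptide,
    pmet_sites: Sequence[int] = (),
    ctx: ChemicalContext | None = None,
    chain: str = "a",
) -> List[FragmentIon]:
    """Linear fragments of a digestion product with fixed mods and terminated
    pMet at the given parent-numbering sites."""
    ctx = ctx or default_context()
    mods = _fixed_mods(peptide, ctx)
    term = ctx.modifications["pmet_terminated"]
    for site in pmet_sites:
        mods.append((peptide.local_position(site), term))
    return fragments_linear(peptide.sequence, mods, ctx, chain=chain)


def fragments_crosslinked(
    species: CrosslinkSpecies,
    site_hypothesis: Tuple[int, int],
    ctx: ChemicalContext | None = None,
) -> List[FragmentIon]:
    """Fragments of an interlink under a (partner residue, pMet site) hypothesis.

    Chain 'a' is the pMet carrier; fragments of either chain containing the
    linked residue carry the full mass of the other chain minus the
    termination shift.  The xl_cleavage pair (alkene carrier / restored
    partner) is appended.
    """
    ctx = ctx or default_context()
    if species.kind != "interlink":
        raise ValueError("cross-linked fragments are defined for interlinks")
    partner_site, pmet_site = site_hypothesis
    a, b = species.peptide_a, species.peptide_b
    assert b is not None
    if not (a.start_index <= pmet_site <= a.end_index) or a.parent.residue_at(
        pmet_site
    ) != "M":
        raise ValueError(f"pMet site {pmet_site} not a Met of chain {a.coords}")
    if not b.start_index <= partner_site <= b.end_index:
        raise ValueError(f"partner site {partner_site} outside chain {b.coords}")
    shift = ctx.pmet_termination_shift
    mass_a = peptide_base_mass(a, ctx)
    mass_b = peptide_base_mass(b, ctx)
    out = fragments_linear(
        a.sequence, _fixed_mods(a, ctx), ctx, chain="a",
        attach=(a.local_position(pmet_site), mass_b - shift),
    )
    out += fragments_linear(
        b.sequence, _fixed_mods(b, ctx), ctx, chain="b",
        attach=(b.local_position(partner_site), mass_a - shift),
    )
    out.append(
        FragmentIon(
            "a", "xl_cleavage_alkene", None, False,
            mass_a - shift + ctx.proton_mass, "a:alkene",
        )
    )
    out.append(
        FragmentIon(
            "b", "xl_cleavage_restored", None, False,
            mass_b + ctx.proton_mass, "b:restored",
        )
    )
    return out


@dataclass
class AnnotationResult:
    matched: List[Tuple[FragmentIon, float, float]]  # (ion, observed, delta)
    unmatched_theoretical: List[FragmentIon]
    unmatched_observed: List[float]


def annotate_spectrum(
    theoretical: Sequence[FragmentIon],
    observed: PeakList | Sequence[float],
    tol_mu: float = DEFAULT_TOL_MU,
) -> AnnotationResult:
    """Greedy nearest matching within +-tol_mu; each observed peak used once."""
    if tol_mu <= 0:
        raise ValueError("tolerance must be positive")
    obs = list(observed.mz) if isinstance(observed, PeakList) else [float(x) for x in observed]
    pairs = [
        (abs(ion.exact_mz - mz), ti, oi)
        for ti, ion in enumerate(theoretical)
        for oi, mz in enumerate(obs)
        if abs(ion.exact_mz - mz) <= tol_mu
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_o: set[int] = set()
    matched = []
    for delta, ti, oi in pairs:
        if ti in used_t or oi in used_o:
            continue
        used_t.add(ti)
        used_o.add(oi)
        matched.append((theoretical[ti], obs[oi], obs[oi] - theoretical[ti].exact_mz))
    return AnnotationResult(
        matched=matched,
        unmatched_theoretical=[f for i, f in enumerate(theoretical) if i not in used_t],
        unmatched_observed=[m for i, m in enumerate(obs) if i not in used_o],
    )


# ---------------------------------------------------------------------------
# localization


@dataclass(frozen=True)
class SiteHypothesis:
    species_id: str
    pmet_site: int
    partner_site: int
    support: int
    conflicts: int

    @property
    def score(self) -> int:
        return self.support - self.conflicts


@dataclass
class LocalizationResult:
    species_ids: Tuple[str, ...]
    hypotheses: Tuple[SiteHypothesis, ...]  # ranked, best first
    verdict: Optional[Tuple[int, int]]  # (partner residue, pMet residue)
    tier: str  # confirmed | weak | ambiguous
    mixture: Optional[Tuple[Tuple[int, ...], ...]] = None


def _tryptic_cterm(peptide: Peptide) -> Optional[int]:
    """Parent index of the peptide's C-terminal K/R when trypsin produced it."""
    if peptide.following and peptide.sequence[-1] in "KR":
        return peptide.end_index
    return None


def _candidate_partner_sites(peptide: Peptide, exclude_tryptic_cterm: bool) -> List[int]:
    excluded = _tryptic_cterm(peptide) if exclude_tryptic_cterm else None
    return [
        i for i in range(peptide.start_index, peptide.end_index + 1) if i != excluded
    ]


def _observed_near(obs: Sequence[float], mass: float, tol: float) -> bool:
    return any(abs(o - mass) <= tol for o in obs)


def localize(
    species: CrosslinkSpecies | Sequence[CrosslinkSpecies],
    observed: PeakList | Sequence[float],
    tol_mu: float = DEFAULT_TOL_MU,
    ctx: ChemicalContext | None = None,
    co_eluting: bool = False,
    exclude_tryptic_cterm: bool = True,
    min_support: int = 2,
) -> LocalizationResult:
    """Rank all site hypotheses for one precursor and return a tiered verdict.

    ``species`` may be a single interlink or the group of mass-coincident
    interpretations of one precursor (e.g. the two reactive-chain readings
    of the m/z 1998 signal).  Only site-determining fragments -- those whose
    mass differs between at least two live hypotheses -- contribute.
    A unique score maximum with support and no conflicts is 'confirmed';
    conflicts, thin support or a co-elution flag cap the tier at 'weak';
    ties are 'ambiguous', never an arbitrary choice.
    """
    ctx = ctx or default_context()
    group = [species] if isinstance(species, CrosslinkSpecies) else list(species)
    if not group:
        raise ValueError("no species to localize")
    if any(s.kind != "interlink" for s in group):
        raise ValueError(
            "localize handles interlinks; use detect_isomer_mixture for monolinks"
        )
    obs = list(observed.mz) if isinstance(observed, PeakList) else [float(x) for x in observed]

    # hypothesis -> {ion key -> exact mass}
    hyp_ions: Dict[Tuple[str, int, int], Dict[tuple, float]] = {}
    for sp in group:
        assert sp.peptide_b is not None
        for (pmet_site,) in sp.placements:
            for partner_site in _candidate_partner_sites(
                sp.peptide_b, exclude_tryptic_cterm
            ):
                ions = fragments_crosslinked(sp, (partner_site, pmet_site), ctx)
                table: Dict[tuple, float] = {}
                for ion in ions:
                    if ion.index is None:
                        key = (ion.series,)  # chain-independent: discriminates
                        # which peptide is the carrier across the group
                    else:
                        pep = sp.peptide_a if ion.chain == "a" else sp.peptide_b
                        key = (pep.start_index, pep.end_index, ion.series, ion.index)
                    table[key] = ion.exact_mz
                hyp_ions[(sp.id, pmet_site, partner_site)] = table

    # site-determining keys: >=2 distinct masses across hypotheses
    all_keys = {k for table in hyp_ions.values() for k in table}
    determining: Dict[tuple, List[float]] = {}
    for key in all_keys:
        masses: List[float] = []
        for table in hyp_ions.values():
            if key not in table:
                continue
            m = table[key]
            if not any(abs(m - x) <= MASS_RESOLUTION for x in masses):
                masses.append(m)
        if len(masses) >= 2:
            determining[key] = masses

    observed_masses = {
        key: [m for m in masses if _observed_near(obs, m, tol_mu)]
        for key, masses in determining.items()
    }

    hypotheses = []
    for (sp_id, pmet_site, partner_site), table in hyp_ions.items():
        support = 0
        conflicts = 0
        for key, seen in observed_masses.items():
            if key not in table or not seen:
                continue
            mine = table[key]
            if any(abs(mine - m) <= tol_mu for m in seen):
                support += 1
            if any(abs(mine - m) > MASS_RESOLUTION for m in seen):
                conflicts += 1
        hypotheses.append(
            SiteHypothesis(sp_id, pmet_site, partner_site, support, conflicts)
        )
    hypotheses.sort(key=lambda h: (-h.score, -h.support, h.partner_site, h.pmet_site))

    verdict: Optional[Tuple[int, int]] = None
    tier = "ambiguous"
    if hypotheses and hypotheses[0].support > 0:
        top = hypotheses[0]
        tied = [
            h for h in hypotheses[1:]
            if h.score == top.score and (h.partner_site, h.pmet_site)
            != (top.partner_site, top.pmet_site)
        ]
        if not tied:
            verdict = (top.partner_site, top.pmet_site)
            if top.conflicts == 0 and top.support >= min_support and not co_eluting:
                tier = "confirmed"
            else:
                tier = "weak"
    return LocalizationResult(
        species_ids=tuple(sp.id for sp in group),
        hypotheses=tuple(hypotheses),
        verdict=verdict,
        tier=tier,
    )


# ---------------------------------------------------------------------------
# positional-isomer mixtures


@dataclass
class IsomerMixtureReport:
    species_id: str
    placements: Tuple[Tuple[Tuple[int, ...], int], ...]  # (sites, exclusive support)
    supported: Tuple[Tuple[int, ...], ...]
    status: str  # mixture | single | undetermined


def detect_isomer_mixture(
    species: CrosslinkSpecies,
    observed: PeakList | Sequence[float],
    tol_mu: float = DEFAULT_TOL_MU,
    ctx: ChemicalContext | None = None,
    min_exclusive: int = 2,
) -> IsomerMixtureReport:
    """Decide which photolysed-site placements of a monolink are present.

    A placement is supported when >=2 of its exclusive fragments (masses no
    alternative placement predicts) are observed; two or more supported
    placements constitute a positional-isomer mixture -- the published
    reading of the m/z 1881.85 species (pMet22 and pMet26 co-occurring).
    """
    ctx = ctx or default_context()
    if len(species.placements) < 2:
        raise ValueError("species has no alternative photolysed-site placements")
    obs = list(observed.mz) if isinstance(observed, PeakList) else [float(x) for x in observed]

    tables = {
        placement: {
            (ion.series, ion.index): ion.exact_mz
            for ion in fragments_peptide(species.peptide_a, placement, ctx)
        }
        for placement in species.placements
    }
    counts = []
    for placement, table in tables.items():
        exclusive = 0
        for key, mass in table.items():
            others = [
                t[key] for p, t in tables.items() if p != placement and key in t
            ]
            if all(abs(mass - o) > MASS_RESOLUTION for o in others) and _observed_near(
                obs, mass, tol_mu
            ):
                exclusive += 1
        counts.append((placement, exclusive))
    supported = tuple(p for p, c in counts if c >= min_exclusive)
    if len(supported) >= 2:
        status = "mixture"
    elif len(supported) == 1:
        status = "single"
    else:
        status = "undetermined"
    return IsomerMixtureReport(
        species_id=species.id,
        placements=tuple(counts),
        supported=supported,
        status=status,
    )


# ---------------------------------------------------------------------------
# spectrum I/O


def read_msms_spectra(path: str | Path) -> List[Tuple[Optional[float], PeakList]]:
    """Read MS/MS spectra from MGF (TITLE/PEPMASS/peak pairs) or 2-col TSV.

    Returns (precursor [M+H]+ or None, PeakList) per spectrum.
    """
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        out = []
        with _mgf.MGF(str(path)) as reader:
            for i, spec in enumerate(reader):
                params = spec.get("params", {})
                pepmass = params.get("pepmass")
                precursor = float(pepmass[0]) if pepmass else None
                title = params.get("title", f"{path.stem}[{i}]")
                peaks = tuple(
                    (float(mz), float(it))
                    for mz, it in zip(spec["m/z array"], spec["intensity array"])
                )
                out.append((precursor, PeakList(label=str(title), peaks=peaks)))
        return out
    from .ms1_match import read_peaklist

    return [(None, read_peaklist(path))]


def write_annotation_tsv(result: AnnotationResult, path: str | Path) -> None:
    lines = ["label\tseries\tindex\tcarries_partner\ttheoretical_mz\tobserved_mz\tdelta_mu"]
    for ion, obs, delta in result.matched:
        lines.append(
            f"{ion.label}\t{ion.series}\t{ion.index if ion.index is not None else ''}\t"
            f"{int(ion.carries_partner)}\t{ion.exact_mz:.4f}\t{obs:.4f}\t{delta:+.4f}"
        )
    for mz in result.unmatched_observed:
        lines.append(f"?\t\t\t\t\t{mz:.4f}\t")
    Path(path).write_text("\n".join(lines) + "\n")
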