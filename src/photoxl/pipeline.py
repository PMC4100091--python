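"""End-to-end orchestration: digest -> candidates -> MS1 match -> control
subtraction -> MS/MS localization -> report and distance restraints.

The pipeline is a pure function of its inputs: given the same protein, peak
lists, spectra and parameters it produces byte-identical reports.  Distance
restraints use the carbene reaction radius (< 5 Angstrom) as the upper
bound; only confirmed residue pairs are exported unless weak pairs are
explicitly requested.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import ChemicalContext, default_context
from .digestion import ProteinSequence, digest, parse_fasta
from .ms1_match import (
    DEFAULT_TOL_PPM,
    MS1Match,
    PeakList,
    match_peaks,
    read_peaklist,
    subtract_control,
)
from .msms import (
    DEFAULT_TOL_MU,
    IsomerMixtureReport,
    LocalizationResult,
    detect_isomer_mixture,
    localize,
    read_msms_spectra,
)
from .xl_candidates import (
    CrosslinkSpecies,
    SpeciesDatabase,
    build_database,
    enumerate_interlinks,
    enumerate_monolinks,
)

log = logging.getLogger("photoxl")

#: side-chain reactive heavy atom per residue, used as the restraint endpoint
#: hint; Calpha is the fallback for residues not listed
SIDECHAIN_ATOM = {
    "M": "SD", "Q": "CG", "N": "CB", "K": "NZ", "R": "NH1",
    "E": "CD", "D": "CG", "S": "OG", "T": "OG1", "C": "SG",
    "Y": "OH", "H": "NE2", "W": "NE1",
}

#: carbene reaction radius, Angstrom
DEFAULT_RESTRAINT_BOUND = 5.0


@dataclass
class RunConfig:
    """Flat, typed run configuration (mirrors the TOML config file)."""

    fasta: Optional[str] = None  # None -> bundled study protein
    first_index: int = 1
    max_missed: int = 2
    min_length: int = 4
    tol_ppm: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOL_PPM))
    ms2_tol_mu: float = DEFAULT_TOL_MU
    adducts: Tuple[str, ...] = ("glycerol_adduct", "sodiated")
    include_intact: bool = False
    exclude_tryptic_cterm: bool = True
    dimer_peaks: Optional[str] = None
    monomer_peaks: Optional[str] = None
    dimer_instrument: str = "maldi_fticr"
    spectra: Tuple[str, ...] = ()
    precursor_window_mu: float = 3.0
    out_dir: Optional[str] = None
    include_weak_restraints: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.tol_ppm.values()) or self.ms2_tol_mu <= 0:
            raise ValueError("all tolerances must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        if "tol_ppm" in raw:
            raw["tol_ppm"] = {**DEFAULT_TOL_PPM, **raw["tol_ppm"]}
        for key in ("adducts", "spectra"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RestraintRecord:
    residue_a: int
    residue_b: int
    atom_hint_a: str
    atom_hint_b: str
    upper_bound: float = DEFAULT_RESTRAINT_BOUND
    tier: str = "confirmed"


@dataclass
class PipelineReport:
    """Everything the run produced, plus tabular views."""

    protein: ProteinSequence
    database: SpeciesDatabase
    matches: List[MS1Match]
    localizations: Dict[float, LocalizationResult]
    mixtures: Dict[float, IsomerMixtureReport]
    table: pd.DataFrame

    def survivors(self) -> List[MS1Match]:
        return [m for m in self.matches if m.status not in ("control_removed", "unassigned")]

    def intermolecular_peaks(self) -> List[MS1Match]:
        """Surviving dimer-band peaks carrying at least one interlink reading."""
        out = []
        for m in self.survivors():
            kinds = {self.database.by_id[a.species_id].kind for a in m.assignments}
            if "interlink" in kinds:
                out.append(m)
        return out

    def confirmed_pairs(self) -> List[Tuple[int, int]]:
        return [
            r.verdict for r in self.localizations.values()
            if r.tier == "confirmed" and r.verdict is not None
        ]

    def summary(self) -> str:
        lines = [
            f"protein: {self.protein.id} "
            f"({self.protein.first_index}..{self.protein.last_index})",
            f"candidate species: {len(self.database)}",
            f"dimer peaks: {len(self.matches)}",
        ]
        for m in self.matches:
            best = f"{m.assignments[0].species_id} ({m.assignments[0].ppm_error:+.2f} ppm)" \
                if m.assignments else "-"
            lines.append(f"  {m.peak:.4f}  {m.status:15s}  {best}")
        lines.append(f"intermolecular cross-link signals: {len(self.intermolecular_peaks())}")
        for peak, res in self.localizations.items():
            v = f"{res.verdict[0]}-{res.verdict[1]}" if res.verdict else "ambiguous"
            lines.append(f"  {peak:.4f}  localized {v}  tier={res.tier}")
        for peak, mix in self.mixtures.items():
            lines.append(
                f"  {peak:.4f}  positional isomers: {mix.status} "
                f"{['+'.join(map(str, p)) for p in mix.supported]}"
            )
        return "\n".join(lines) + "\n"


def build_candidates(
    protein: ProteinSequence,
    max_missed: int = 2,
    min_length: int = 4,
    adducts: Sequence[str] = ("glycerol_adduct", "sodiated"),
    include_intact: bool = False,
    ctx: ChemicalContext | None = None,
) -> SpeciesDatabase:
    """Digest a protein and index every candidate cross-linked species."""
    ctx = ctx or default_context()
    peptides = digest(protein, max_missed=max_missed, min_length=min_length)
    if not peptides:
        raise ValueError("digestion produced no peptides")
    adduct_mods = [ctx.modifications[a] for a in adducts]
    species = enumerate_interlinks(peptides, ctx)
    species += enumerate_monolinks(peptides, adduct_mods, ctx)
    if include_intact:
        # unphotolysed diazirine survivors (+8.0341 u per intact pMet site)
        intact = ctx.modifications["pmet_intact"]
        from .digestion import met_sites
        from .xl_candidates import peptide_base_mass
        import itertools as _it

        for pep in peptides:
            sites = met_sites(pep)
            m0 = peptide_base_mass(pep, ctx)
            for k in range(1, len(sites) + 1):
                species.append(
                    CrosslinkSpecies(
                        id=f"IN:{pep.coords}|k{k}",
                        kind="monolink_intact",
                        peptide_a=pep,
                        peptide_b=None,
                        placements=tuple(_it.combinations(sites, k)),
                        neutral_mass=m0 + k * intact.delta_mass,
                        extra_mods=("pmet_intact",),
                    )
                )
    return build_database(species, ctx)


def run_analysis(
    protein: ProteinSequence,
    dimer_peaks: PeakList,
    monomer_peaks: Optional[PeakList] = None,
    spectra: Sequence[Tuple[Optional[float], PeakList]] = (),
    max_missed: int = 2,
    min_length: int = 4,
    tol_ppm: Optional[float] = None,
    ms2_tol_mu: float = DEFAULT_TOL_MU,
    adducts: Sequence[str] = ("glycerol_adduct", "sodiated"),
    include_intact: bool = False,
    exclude_tryptic_cterm: bool = True,
    precursor_window_mu: float = 3.0,
    ctx: ChemicalContext | None = None,
) -> PipelineReport:
    """The in-memory pipeline behind :func:`run_pipeline` (and the simulator)."""
    ctx = ctx or default_context()
    db = build_candidates(
        protein, max_missed, min_length, adducts, include_intact, ctx
    )
    matches = match_peaks(db, dimer_peaks, tol_ppm)
    if monomer_peaks is not None and len(monomer_peaks):
        tol = tol_ppm if tol_ppm is not None else dimer_peaks.default_tol_ppm
        matches = subtract_control(matches, monomer_peaks, tol)
    for m in matches:
        if m.status == "control_removed":
            log.info("peak %.4f removed: present in monomer-band control", m.peak)
        elif m.status == "unassigned":
            log.info("peak %.4f unassigned within tolerance", m.peak)

    localizations: Dict[float, LocalizationResult] = {}
    mixtures: Dict[float, IsomerMixtureReport] = {}
    for m in matches:
        spectrum = _find_spectrum(spectra, m.peak, precursor_window_mu)
        if spectrum is None or not m.assignments:
            continue
        assigned = [db.by_id[a.species_id] for a in m.assignments]
        interlinks = [s for s in assigned if s.kind == "interlink"]
        if m.status != "control_removed" and interlinks:
            localizations[m.peak] = localize(
                interlinks,
                spectrum,
                ms2_tol_mu,
                ctx,
                exclude_tryptic_cterm=exclude_tryptic_cterm,
            )
        for sp in assigned:
            if sp.kind in ("monolink_terminated", "adducted_monolink") and len(
                sp.placements
            ) >= 2:
                mixtures[m.peak] = detect_isomer_mixture(sp, spectrum, ms2_tol_mu, ctx)
                break

    table = _report_table(db, matches, localizations, ctx)
    return PipelineReport(protein, db, matches, localizations, mixtures, table)


def _find_spectrum(
    spectra: Sequence[Tuple[Optional[float], PeakList]],
    peak: float,
    window_mu: float,
) -> Optional[PeakList]:
    best = None
    best_d = window_mu
    for precursor, pl in spectra:
        if precursor is None:
            continue
        d = abs(precursor - peak)
        if d <= best_d:
            best, best_d = pl, d
    return best


def _report_table(
    db: SpeciesDatabase,
    matches: Sequence[MS1Match],
    localizations: Dict[float, LocalizationResult],
    ctx: ChemicalContext,
) -> pd.DataFrame:
    rows = []
    for m in matches:
        loc = localizations.get(m.peak)
        if not m.assignments:
            rows.append(
                dict(
                    peak_mz=round(m.peak, 6), theoretical_mz=None, ppm_error=None,
                    species_id=None, kind=None, chain_a=None, chain_b=None,
                    status=m.status, verdict=None, tier=None,
                )
            )
            continue
        for a in m.assignments:
            sp = db.by_id[a.species_id]
            verdict = tier = None
            if loc is not None and sp.kind == "interlink":
                verdict = (
                    f"{loc.verdict[0]}-{loc.verdict[1]}" if loc.verdict else "ambiguous"
                )
                tier = loc.tier
            rows.append(
                dict(
                    peak_mz=round(m.peak, 6),
                    theoretical_mz=round(sp.mz(ctx), 6),
                    ppm_error=round(a.ppm_error, 4),
                    species_id=sp.id,
                    kind=sp.kind,
                    chain_a=f"{sp.peptide_a.coords}:{sp.peptide_a.sequence}",
                    chain_b=(
                        f"{sp.peptide_b.coords}:{sp.peptide_b.sequence}"
                        if sp.peptide_b else None
                    ),
                    status=m.status,
                    verdict=verdict,
                    tier=tier,
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """File-driven pipeline entry point; deterministic given the config."""
    ctx = default_context()
    if config.fasta is not None:
        if not Path(config.fasta).exists():
            raise FileNotFoundError(config.fasta)
        protein = parse_fasta(config.fasta, first_index=config.first_index)[0]
    else:
        from .study import study_protein

        protein = study_protein()
    if config.dimer_peaks is None:
        raise ValueError("config.dimer_peaks is required")
    dimer = read_peaklist(
        config.dimer_peaks, band="dimer", instrument=config.dimer_instrument
    )
    monomer = None
    if config.monomer_peaks is not None:
        monomer = read_peaklist(
            config.monomer_peaks, band="monomer", instrument=config.dimer_instrument
        )
    spectra: List[Tuple[Optional[float], PeakList]] = []
    for path in config.spectra:
        spectra.extend(read_msms_spectra(path))
    report = run_analysis(
        protein,
        dimer,
        monomer,
        spectra,
        max_missed=config.max_missed,
        min_length=config.min_length,
        tol_ppm=config.tol_ppm.get(config.dimer_instrument),
        ms2_tol_mu=config.ms2_tol_mu,
        adducts=config.adducts,
        include_intact=config.include_intact,
        exclude_tryptic_cterm=config.exclude_tryptic_cterm,
        precursor_window_mu=config.precursor_window_mu,
        ctx=ctx,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir, config.include_weak_restraints)
    return report


def export_restraints(
    report: PipelineReport,
    upper_bound: float = DEFAULT_RESTRAINT_BOUND,
    include_weak: bool = False,
) -> List[RestraintRecord]:
    """Distance restraints from localized pairs (confirmed only by default)."""
    records = []
    seen = set()
    for res in report.localizations.values():
        if res.verdict is None:
            continue
        if res.tier != "confirmed" and not (include_weak and res.tier == "weak"):
            continue
        ra, rb = res.verdict
        if (ra, rb) in seen:
            continue
        seen.add((ra, rb))
        records.append(
            RestraintRecord(
                residue_a=ra,
                residue_b=rb,
                atom_hint_a=SIDECHAIN_ATOM.get(report.protein.residue_at(ra), "CA"),
                atom_hint_b=SIDECHAIN_ATOM.get(report.protein.residue_at(rb), "CA"),
                upper_bound=upper_bound,
                tier=res.tier,
            )
        )
    return records


def write_restraints(records: Sequence[RestraintRecord], path: str | Path) -> None:
    lines = ["residue_a\tresidue_b\tatom_hint_a\tatom_hint_b\tupper_bound_A\ttier\tassign"]
    for r in records:
        assign = (
            f"assign (resid {r.residue_a} and name {r.atom_hint_a}) "
            f"(resid {r.residue_b} and name {r.atom_hint_b}) {r.upper_bound:.1f} {r.upper_bound:.1f} 0.0"
        )
        lines.append(
            f"{r.residue_a}\t{r.residue_b}\t{r.atom_hint_a}\t{r.atom_hint_b}"
            f"\t{r.upper_bound:.1f}\t{r.tier}\t{assign}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(
    report: PipelineReport, out_dir: str | Path, include_weak: bool = False
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6f")
    (out / "summary.txt").write_text(report.summary())
    write_restraints(export_restraints(report, include_weak=include_weak),
                     out / "restraints.tsv")
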