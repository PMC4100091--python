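"""Ground-truthed synthetic photo-cross-linking experiments.

The study's raw peak lists were never deposited, so every stage of the
pipeline is exercised against simulated data with the same statistical
structure the analysis assumes:

* the monomer band carries the intramolecular chemistry -- dead ends,
  loop-links, adducts -- for Met-bearing peptides that photolysed;
* the dimer band carries everything the monomer band carries plus one
  interlink mass per planted residue contact (and its missed-cleavage
  variants);
* all m/z values receive multiplicative Gaussian ppm error (the tolerance
  semantics of FTICR instruments are relative, so the noise model is too);
* MS/MS spectra sample the theoretical fragments of the true site
  hypothesis at a given coverage probability;
* decoy peaks are tryptic peptides of a shuffled sequence: realistic
  masses that cannot be true positives.

Everything is deterministic given the seed; there is no hidden global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import ChemicalContext, default_context
from .digestion import Peptide, ProteinSequence, digest, met_sites
from .ms1_match import PeakList
from .msms import fragments_crosslinked
from .pipeline import PipelineReport, run_analysis
from .xl_candidates import (
    CrosslinkSpecies,
    enumerate_interlinks,
    enumerate_monolinks,
)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Specification of one simulated experiment.

    true_contacts are (partner residue, pMet residue) pairs across the two
    chains of the dimer; each pMet residue must be a Met.  photolysis_yield
    is the fraction of pMet-bearing species that photolysed (inclusion
    probability per monomer-band species); ppm_sigma the Gaussian m/z error
    scale; fragment_coverage the probability a theoretical fragment appears
    in an MS/MS spectrum; contaminants the number of decoy peaks.
    """

    protein: ProteinSequence
    true_contacts: Tuple[Tuple[int, int], ...]
    seed: int
    photolysis_yield: float = 0.5
    ppm_sigma: float = 0.5
    fragment_coverage: float = 0.9
    contaminants: int = 5
    max_missed: int = 1
    adducts: Tuple[str, ...] = ("glycerol_adduct", "sodiated")
    min_length: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.photolysis_yield <= 1:
            raise ValueError("photolysis_yield must be in (0, 1]")
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        if not 0 < self.fragment_coverage <= 1:
            raise ValueError("fragment_coverage must be in (0, 1]")
        for partner, pmet in self.true_contacts:
            if self.protein.residue_at(pmet) != "M":
                raise ValueError(
                    f"contact ({partner}, {pmet}): residue {pmet} is "
                    f"{self.protein.residue_at(pmet)}, not Met"
                )


@dataclass
class TruthRecord:
    contact: Tuple[int, int]  # (partner residue, pMet residue)
    species_ids: Tuple[str, ...]  # interlink species carrying this contact
    mz: Tuple[float, ...]  # their theoretical [M+H]+


@dataclass
class SimulatedExperiment:
    spec: SyntheticExperiment
    monomer: PeakList
    dimer: PeakList
    spectra: List[Tuple[float, PeakList]]
    truth: List[TruthRecord]


def _perturb(rng: np.random.Generator, mz: float, ppm_sigma: float) -> float:
    return mz * (1 + rng.normal(0.0, ppm_sigma) * 1e-6) if ppm_sigma > 0 else mz


def _contact_species(
    peptides: Sequence[Peptide],
    contact: Tuple[int, int],
    ctx: ChemicalContext,
) -> List[CrosslinkSpecies]:
    """All interlink species realizing a contact: the pMet residue photolysed
    on a carrier peptide containing it, inserted at a partner peptide
    containing the partner residue away from its tryptic C-terminus."""
    partner_res, pmet_res = contact
    out = []
    for sp in enumerate_interlinks(peptides, ctx):
        a, b = sp.peptide_a, sp.peptide_b
        assert b is not None
        if sp.pmet_site != pmet_res:
            continue
        if not b.start_index <= partner_res <= b.end_index:
            continue
        if b.following and b.sequence[-1] in "KR" and partner_res == b.end_index:
            continue  # link on the cleaved C-terminal K/R is not producible
        out.append(sp)
    return out


def simulate_experiment(
    spec: SyntheticExperiment, ctx: ChemicalContext | None = None
) -> SimulatedExperiment:
    """Generate monomer/dimer MS1 peak lists, MS/MS spectra and the truth table."""
    ctx = ctx or default_context()
    rng = np.random.default_rng(spec.seed)
    peptides = digest(
        spec.protein, max_missed=spec.max_missed, min_length=spec.min_length
    )

    # monomer band: intramolecular chemistry, one species class at a time
    adduct_mods = [ctx.modifications[a] for a in spec.adducts]
    monolinks = enumerate_monolinks(peptides, adduct_mods, ctx)
    monomer_masses: List[float] = []
    seen_mass: List[float] = []
    for sp in monolinks:
        # isobaric twins (dead end / loop-link) produce one signal
        if any(abs(sp.neutral_mass - m) < 1e-9 for m in seen_mass):
            continue
        seen_mass.append(sp.neutral_mass)
        if rng.random() < spec.photolysis_yield:
            monomer_masses.append(sp.mz(ctx))

    # dimer band: interlinks for planted contacts + everything intramolecular
    truth: List[TruthRecord] = []
    interlink_mzs: List[float] = []
    for contact in spec.true_contacts:
        realizations = _contact_species(peptides, contact, ctx)
        if not realizations:
            raise ValueError(f"contact {contact} has no tryptic realization")
        truth.append(
            TruthRecord(
                contact=contact,
                species_ids=tuple(s.id for s in realizations),
                mz=tuple(s.mz(ctx) for s in realizations),
            )
        )
        interlink_mzs.extend(s.mz(ctx) for s in realizations)

    # decoys: tryptic peptides of a shuffled sequence
    shuffled = "".join(
        rng.permutation(list(spec.protein.residues)).tolist()
    )
    decoy_protein = ProteinSequence(
        id="decoy", residues=shuffled, first_index=1,
        fixed_mods=spec.protein.fixed_mods,
    )
    decoy_peps = digest(decoy_protein, max_missed=0, min_length=spec.min_length)
    from .xl_candidates import peptide_base_mass

    decoy_mzs = [
        ctx.mz_singly_protonated(peptide_base_mass(p, ctx))
        for p in decoy_peps
    ]
    decoys = (
        [decoy_mzs[i] for i in rng.choice(len(decoy_mzs),
                                          size=min(spec.contaminants, len(decoy_mzs)),
                                          replace=False)]
        if spec.contaminants else []
    )

    monomer = PeakList(
        label=f"sim_monomer_seed{spec.seed}",
        peaks=tuple(_perturb(rng, m, spec.ppm_sigma) for m in monomer_masses),
        band="monomer",
        instrument="maldi_fticr",
    )
    dimer = PeakList(
        label=f"sim_dimer_seed{spec.seed}",
        peaks=tuple(
            _perturb(rng, m, spec.ppm_sigma)
            for m in interlink_mzs + monomer_masses + decoys
        ),
        band="dimer",
        instrument="maldi_fticr",
    )

    # MS/MS for the base (fewest missed cleavages) realization of each contact
    spectra: List[Tuple[float, PeakList]] = []
    for rec, contact in zip(truth, spec.true_contacts):
        species = {
            sid: mz for sid, mz in zip(rec.species_ids, rec.mz)
        }
        base_id = min(
            rec.species_ids,
            key=lambda sid: len(sid),  # fewest coordinates ~ fewest missed
        )
        base = next(
            s for s in _contact_species(peptides, contact, ctx) if s.id == base_id
        )
        ions = fragments_crosslinked(base, contact, ctx)
        masses = [
            _perturb(rng, ion.exact_mz, spec.ppm_sigma)
            for ion in ions
            if rng.random() < spec.fragment_coverage
        ]
        if masses:
            spectra.append(
                (
                    species[base_id],
                    PeakList(label=f"sim_msms_{base_id}", peaks=tuple(masses)),
                )
            )
    return SimulatedExperiment(
        spec=spec, monomer=monomer, dimer=dimer, spectra=spectra, truth=truth
    )


def run_simulated(
    sim: SimulatedExperiment,
    tol_ppm: float = 2.0,
    ms2_tol_mu: float = 0.5,
    ctx: ChemicalContext | None = None,
) -> PipelineReport:
    """Run the standard pipeline on a simulated experiment."""
    return run_analysis(
        sim.spec.protein,
        sim.dimer,
        sim.monomer,
        sim.spectra,
        max_missed=sim.spec.max_missed,
        min_length=sim.spec.min_length,
        tol_ppm=tol_ppm,
        ms2_tol_mu=ms2_tol_mu,
        adducts=sim.spec.adducts,
        ctx=ctx,
    )


@dataclass
class RecoveryMetrics:
    recovery: Optional[float]  # fraction of planted contacts recovered; None if no truth
    recovered: Tuple[Tuple[int, int], ...]
    false_positives: int  # confirmed pairs not planted
    tier_counts: Dict[str, int]


def recovery_assessment(
    truth: Sequence[TruthRecord], report: PipelineReport
) -> RecoveryMetrics:
    """Pair-exact recovery of planted contacts from a pipeline report."""
    verdicts = {
        res.verdict: res.tier
        for res in report.localizations.values()
        if res.verdict is not None
    }
    tier_counts: Dict[str, int] = {}
    for res in report.localizations.values():
        tier_counts[res.tier] = tier_counts.get(res.tier, 0) + 1
    planted = [rec.contact for rec in truth]
    recovered = tuple(c for c in planted if c in verdicts)
    false_positives = sum(
        1 for pair, tier in verdicts.items()
        if tier == "confirmed" and pair not in planted
    )
    return RecoveryMetrics(
        recovery=len(recovered) / len(planted) if planted else None,
        recovered=recovered,
        false_positives=false_positives,
        tier_counts=tier_counts,
    )
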