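"""MS1 peak matching against the candidate database and monomer-control subtraction.

The homodimer gel band contains every species the monomer band contains
(dead ends, loop-links, adducts -- all intramolecular chemistry) plus the
intermolecular interlinks that only a covalent dimer can produce.  Peaks
from the dimer band are therefore matched within a ppm window and any peak
also present in a monomer-band control list is struck out; the survivors
are the intermolecular cross-links.

Default tolerances follow the two instrument classes used in the study:
40 ppm for MALDI-TOF peptide fingerprints, 2 ppm for FTICR detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .xl_candidates import SpeciesDatabase

BANDS = ("monomer", "dimer", "other")
INSTRUMENTS = ("maldi_tof", "maldi_fticr", "lc_esi_fticr")

#: per-instrument MS1 matching tolerance (ppm)
DEFAULT_TOL_PPM = {"maldi_tof": 40.0, "maldi_fticr": 2.0, "lc_esi_fticr": 2.0}

#: peaks closer than this are considered one signal and merged
MERGE_PPM = 0.1


@dataclass(frozen=True)
class PeakList:
    """Observed [M+H]+ monoisotopic peaks from one gel band / instrument run."""

    label: str
    peaks: tuple  # of (mz, intensity|None)
    band: str = "other"
    instrument: str = "maldi_fticr"

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        normalized = _normalize(self.peaks)
        object.__setattr__(self, "peaks", normalized)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def default_tol_ppm(self) -> float:
        return DEFAULT_TOL_PPM[self.instrument]


def _normalize(peaks: Iterable) -> tuple:
    """Sort by m/z, validate positivity, merge peaks within MERGE_PPM."""
    cleaned: List[Tuple[float, Optional[float]]] = []
    for p in peaks:
        if isinstance(p, (int, float)):
            mz, inten = float(p), None
        else:
            mz = float(p[0])
            inten = float(p[1]) if len(p) > 1 and p[1] is not None else None
        if mz <= 0:
            raise ValueError(f"non-positive m/z {mz}")
        cleaned.append((mz, inten))
    cleaned.sort(key=lambda p: p[0])
    merged: List[Tuple[float, Optional[float]]] = []
    for mz, inten in cleaned:
        if merged and (mz - merged[-1][0]) / merged[-1][0] * 1e6 <= MERGE_PPM:
            prev_mz, prev_int = merged[-1]
            tot = (prev_int or 0.0) + (inten or 0.0)
            merged[-1] = ((prev_mz + mz) / 2, tot if (prev_int or inten) else None)
        else:
            merged.append((mz, inten))
    return tuple(merged)


def read_peaklist(
    source: str | Path | TextIO,
    label: str | None = None,
    band: str = "other",
    instrument: str = "maldi_fticr",
) -> PeakList:
    """Read a 1- or 2-column TSV of (mz [, intensity]); '#' starts a comment."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        label = label or Path(source).stem
    else:
        text = source.read()
        label = label or "peaklist"
    peaks = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace(",", "\t").split()
        mz = float(fields[0])
        inten = float(fields[1]) if len(fields) > 1 else None
        peaks.append((mz, inten))
    return PeakList(label=label, peaks=tuple(peaks), band=band, instrument=instrument)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    lines = [f"# {peaklist.label} band={peaklist.band} instrument={peaklist.instrument}"]
    for mz, inten in peaklist.peaks:
        lines.append(f"{mz:.4f}" if inten is None else f"{mz:.4f}\t{inten:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Assignment:
    species_id: str
    ppm_error: float


@dataclass(frozen=True)
class MS1Match:
    """One observed peak with its candidate assignments and status.

    Status is 'ambiguous' only when the assignments span >=2 distinct
    species after isobaric grouping (a dead-end and its loop-link twin are
    one interpretation; the two reactive-chain readings of an interlink are
    genuinely distinct and stay ambiguous until MS/MS).
    """

    peak: float
    assignments: Tuple[Assignment, ...]
    status: str  # unassigned | unique | ambiguous | control_removed


def _isobaric_groups(db: SpeciesDatabase, ids: Sequence[str]) -> int:
    """Number of interpretation groups among assigned ids (union by isobaric_with)."""
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in ids:
        for j in db.by_id[i].isobaric_with:
            if j in parent:
                parent[find(i)] = find(j)
    return len({find(i) for i in ids})


def match_peaks(
    db: SpeciesDatabase, peaks: PeakList, tol_ppm: float | None = None
) -> List[MS1Match]:
    """Annotate every peak with all species within the ppm window (signed errors)."""
    if len(db) == 0:
        raise ValueError("empty candidate database")
    tol = peaks.default_tol_ppm if tol_ppm is None else tol_ppm
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    ctx = db.ctx
    matches = []
    for mz, _ in peaks.peaks:
        hits = db.query_mz(mz, tol)
        assignments = tuple(
            Assignment(s.id, ctx.ppm_error(mz, s.mz(ctx)))
            for s in sorted(hits, key=lambda s: abs(mz - s.mz(ctx)))
        )
        if not assignments:
            status = "unassigned"
        elif _isobaric_groups(db, [a.species_id for a in assignments]) > 1:
            status = "ambiguous"
        else:
            status = "unique"
        matches.append(MS1Match(peak=mz, assignments=assignments, status=status))
    return matches


def subtract_control(
    dimer_matches: Sequence[MS1Match],
    monomer_peaks: PeakList,
    tol_ppm: float | None = None,
) -> List[MS1Match]:
    """Strike out dimer peaks also present in a monomer-band control.

    Comparison is peak-level (not species-level): the study removed every
    dimer-band signal found in either monomer band as intramolecular,
    regardless of interpretation.  Idempotent; survivors keep their status.
    """
    tol = monomer_peaks.default_tol_ppm if tol_ppm is None else tol_ppm
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    control = monomer_peaks.mz
    out = []
    for m in dimer_matches:
        if control.size and np.min(np.abs(control - m.peak)) / m.peak * 1e6 <= tol:
            out.append(replace(m, status="control_removed"))
        else:
            out.append(m)
    return out
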