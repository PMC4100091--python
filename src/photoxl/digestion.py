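"""Protein sequences with tag-aware numbering and in-silico tryptic digestion.

The study protein (14-3-3zeta, UniProt P63104) carries three extra residues
left by thrombin cleavage of its His tag, numbered (-2)GSH(0); Met1 of the
native sequence keeps index 1.  Residue numbering is therefore a run of
consecutive integers starting at ``first_index`` -- which may be negative,
and index 0 is a legal position.  All coordinates reported anywhere in this
package are parent-sequence indices in that numbering, never 0-based array
offsets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, TextIO

from Bio import SeqIO

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein with an explicit numbering offset and fixed modifications."""

    id: str
    residues: str
    first_index: int = 1
    fixed_mods: tuple[str, ...] = ("cam",)

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_RESIDUES
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {self.id!r}")

    @property
    def last_index(self) -> int:
        return self.first_index + len(self.residues) - 1

    def offset(self, index: int) -> int:
        """0-based string offset of a residue index."""
        if not self.first_index <= index <= self.last_index:
            raise IndexError(f"residue index {index} outside {self.id}")
        return index - self.first_index

    def residue_at(self, index: int) -> str:
        return self.residues[self.offset(index)]


@dataclass(frozen=True)
class Peptide:
    """A digestion product; start/end are inclusive parent-numbering indices."""

    parent: ProteinSequence
    start_index: int
    end_index: int
    missed_cleavages: int
    preceding: str = ""  # residue before the peptide, '' at protein N-terminus
    following: str = ""  # residue after the peptide, '' at protein C-terminus

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("end_index before start_index")

    @property
    def sequence(self) -> str:
        p = self.parent
        return p.residues[p.offset(self.start_index) : p.offset(self.end_index) + 1]

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    def local_position(self, index: int) -> int:
        """1-based position within the peptide of a parent residue index."""
        if not self.start_index <= index <= self.end_index:
            raise IndexError(f"residue {index} not in peptide {self.coords}")
        return index - self.start_index + 1

    @property
    def coords(self) -> str:
        return f"{self.start_index}-{self.end_index}"

    def __str__(self) -> str:  # Table-2 style "4-9 K.NELVQK.A"
        pre = self.preceding or ""
        fol = self.following or ""
        return f"{self.coords} {pre}.{self.sequence}.{fol}"


def parse_fasta(
    source: str | Path | TextIO,
    first_index: int = 1,
    fixed_mods: Sequence[str] = ("cam",),
) -> List[ProteinSequence]:
    """Read a (multi-record) FASTA into ProteinSequence objects.

    Sequences are uppercased; ambiguous or non-standard residues raise.
    The numbering offset applies to every record (supply records separately
    when they differ).
    """
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper().strip("*")
        out.append(
            ProteinSequence(
                id=rec.id, residues=seq, first_index=first_index,
                fixed_mods=tuple(fixed_mods),
            )
        )
    return out


def cleavage_offsets(residues: str, suppress_proline: bool = True) -> List[int]:
    """0-based offsets after which trypsin cleaves (C-terminal to K/R, not before P)."""
    sites = []
    for i, aa in enumerate(residues[:-1]):
        if aa in "KR" and not (suppress_proline and residues[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    protein: ProteinSequence,
    max_missed: int = 2,
    min_length: int = 1,
    suppress_proline: bool = True,
) -> List[Peptide]:
    """All tryptic peptides with 0..max_missed missed cleavages.

    The protein N-terminal peptide is included regardless of preceding
    context, and the C-terminal peptide regardless of its last residue.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    res = protein.residues
    sites = cleavage_offsets(res, suppress_proline)
    # fragment boundaries as 0-based [start, end] offsets
    starts = [0] + [s + 1 for s in sites]
    ends = sites + [len(res) - 1]
    peptides = []
    for i, start in enumerate(starts):
        for missed in range(0, max_missed + 1):
            j = i + missed
            if j >= len(ends):
                break
            end = ends[j]
            if end - start + 1 < min_length:
                continue
            peptides.append(
                Peptide(
                    parent=protein,
                    start_index=start + protein.first_index,
                    end_index=end + protein.first_index,
                    missed_cleavages=missed,
                    preceding=res[start - 1] if start > 0 else "",
                    following=res[end + 1] if end + 1 < len(res) else "",
                )
            )
    return peptides


def met_sites(peptide: Peptide) -> List[int]:
    """Parent-numbering indices of all Met residues in the peptide."""
    return [
        peptide.start_index + i
        for i, aa in enumerate(peptide.sequence)
        if aa == "M"
    ]
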