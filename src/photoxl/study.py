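"""Reference inputs for the 14-3-3zeta homodimer photo-cross-linking study.

The raw instrument files of the study were never deposited; what is public
are the printed peak values: the MALDI-TOF and FTICR [M+H]+ signals of the
dimer- and monomer-band digests, and the integer fragment labels of the
MS/MS spectra.  This module embeds those published values and rebuilds the
spectra at exact theoretical m/z -- each printed integer label identifies a
fragment ion whose exact mass the package recomputes (printed labels mix
floor and round conventions, so both are accepted when selecting ions).

The protein is human 14-3-3zeta (UniProt P63104, 245 residues) with the
three tag residues (-2)GSH(0) left by thrombin cleavage; Met1 keeps index 1.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

from .chem import ChemicalContext, default_context
from .digestion import Peptide, ProteinSequence, digest
from .ms1_match import PeakList
from .msms import FragmentIon, fragments_crosslinked, fragments_peptide
from .xl_candidates import (
    CrosslinkSpecies,
    SpeciesDatabase,
    build_database,
    enumerate_interlinks,
    enumerate_monolinks,
)

#: canonical P63104 sequence (245 aa)
P63104_SEQUENCE = (
    "MDKNELVQKAKLAEQAERYDDMAACMKSVTEQGAELSNEERNLLSVAYKNVVGARRSSWRVVSSIEQK"
    "TEGAEKKQQMAREYREKIETELRDICNDVLSLLEKFLIPNASQAESKVFYLKMKGDYYRYLAEVAAGD"
    "DKKGIVDQSQQAYQEALEISKKEMQPTHPIRLGLALNFSVFYYEILNSPEKACSLAKTAFDEAIAELD"
    "TLSEESYKDSTLIMQLLRDNLTLWTSDTQGDEAEAGEGGEN"
)

#: tag residues left by thrombin cleavage of the His tag, numbered (-2)..(0)
TAG = "GSH"
FIRST_INDEX = -2

#: study digestion conditions (missed cleavages seen in the data, short-peptide floor)
MAX_MISSED = 2
MIN_LENGTH = 4

# printed [M+H]+ values -----------------------------------------------------

#: dimer-band signals by MALDI-TOF (Table of intermolecular cross-links)
DIMER_XL_MALDI_TOF = (1342.744, 1470.824, 1998.030)
#: the same three signals at FTICR accuracy
DIMER_XL_FTICR = (1342.7457, 1470.8408, 1998.0186)
#: monomer-band species (dead ends / loop-links / glycerol-Na adduct)
MONOMER_SPECIES_FTICR = (1861.8735, 1881.8459, 1995.8791)

# printed integer fragment labels per MS/MS spectrum ------------------------

FIG3A_LABELS = (244, 357, 456, 613, 1214)
FIG3B_LABELS = (175, 244, 246, 357, 456, 741, 1086, 1214, 1342)
FIG3C_LABELS = (413, 528, 613, 656, 770, 899, 1012, 1111, 1229, 1343, 1385, 1471, 1586)
FIG4B_ISOMER_LABELS = (258, 418, 438, 489, 509, 580)
FIG4B_BSERIES_LABELS = (314, 442, 513, 642, 798, 961, 1076, 1191)


def study_protein() -> ProteinSequence:
    return ProteinSequence(
        id="P63104_tagged",
        residues=TAG + P63104_SEQUENCE,
        first_index=FIRST_INDEX,
        fixed_mods=("cam",),
    )


def study_peptides(
    max_missed: int = MAX_MISSED, min_length: int = MIN_LENGTH
) -> List[Peptide]:
    return digest(study_protein(), max_missed=max_missed, min_length=min_length)


def study_species(
    max_missed: int = MAX_MISSED,
    min_length: int = MIN_LENGTH,
    ctx: ChemicalContext | None = None,
) -> List[CrosslinkSpecies]:
    """Full candidate list: all interlinks plus dead ends, loop-links and the
    glycerol / glycerol+Na adducts observed in stored samples."""
    ctx = ctx or default_context()
    peptides = study_peptides(max_missed, min_length)
    adducts = [ctx.modifications["glycerol_adduct"], ctx.modifications["sodiated"]]
    return enumerate_interlinks(peptides, ctx) + enumerate_monolinks(
        peptides, adducts, ctx
    )


def study_database(
    max_missed: int = MAX_MISSED,
    min_length: int = MIN_LENGTH,
    ctx: ChemicalContext | None = None,
) -> SpeciesDatabase:
    ctx = ctx or default_context()
    return build_database(study_species(max_missed, min_length, ctx), ctx)


# identified species --------------------------------------------------------

SPECIES_1342 = "IL:76-80|4-9|pM78"  # QQpMAR x NELVQK
SPECIES_1470 = "IL:75-80|4-9|pM78"  # KQQpMAR x NELVQK
SPECIES_1998_A = "IL:76-80|-2-9|pM78"  # QQpMAR x GSHMDKNELVQK
SPECIES_1998_B = "IL:-2-9|76-80|pM1"  # GSHpMDKNELVQK x QQMAR
SPECIES_1881 = "ML:12-27|k1"  # LAEQAERYDD(pM)AAC(pM)K, one site photolysed
SPECIES_1861 = "ML:12-27|k2"  # both sites photolysed
SPECIES_1995 = "AD:12-27|k1|glycerol_adduct+sodiated"

#: the cross-linked residue pair localized by the study (Gln8 - pMet78)
TRUE_CONTACT = (8, 78)


def dimer_peaklist(instrument: str = "maldi_tof") -> PeakList:
    """Dimer-band peak list reconstructed from printed values.

    The dimer band contains the interlink signals plus everything the
    monomer band contains (intramolecular chemistry happens in both).
    """
    xl = DIMER_XL_MALDI_TOF if instrument == "maldi_tof" else DIMER_XL_FTICR
    return PeakList(
        label=f"dimer_band_{instrument}",
        peaks=tuple(xl) + tuple(MONOMER_SPECIES_FTICR),
        band="dimer",
        instrument=instrument,
    )


def monomer_peaklist(instrument: str = "maldi_tof") -> PeakList:
    return PeakList(
        label=f"monomer_band_{instrument}",
        peaks=tuple(MONOMER_SPECIES_FTICR),
        band="monomer",
        instrument=instrument,
    )


# reconstructed MS/MS spectra ------------------------------------------------


def _select_by_labels(
    ions: Sequence[FragmentIon], labels: Sequence[int]
) -> List[float]:
    """Exact masses of the ions a printed integer label list identifies.

    Printed labels mix floor (1214.69 -> 1214) and round (1228.70 -> 1229)
    conventions, so an ion matches a label when either agrees.  Every label
    must resolve to at least one ion.
    """
    out: List[float] = []
    for label in labels:
        hits = [
            ion.exact_mz
            for ion in ions
            if math.floor(ion.exact_mz) == label or round(ion.exact_mz) == label
        ]
        if not hits:
            raise ValueError(f"printed label {label} matches no theoretical ion")
        for mz in hits:
            if all(abs(mz - x) > 1e-9 for x in out):
                out.append(mz)
    return sorted(out)


def _spectrum(
    label: str, masses: Sequence[float], precursor: float
) -> Tuple[float, PeakList]:
    return precursor, PeakList(label=label, peaks=tuple(masses), band="dimer")


def fig3a_spectrum(
    db: SpeciesDatabase, ctx: ChemicalContext | None = None
) -> Tuple[float, PeakList]:
    """MS/MS of the 1342.75 precursor (QQpMAR x NELVQK, link at Gln8)."""
    ctx = ctx or default_context()
    ions = fragments_crosslinked(db.by_id[SPECIES_1342], TRUE_CONTACT, ctx)
    return _spectrum(
        "fig3a_1342", _select_by_labels(ions, FIG3A_LABELS), DIMER_XL_FTICR[0]
    )


def fig3b_spectrum(
    db: SpeciesDatabase, ctx: ChemicalContext | None = None
) -> Tuple[float, PeakList]:
    """MS/MS of the 1470.84 precursor (KQQpMAR x NELVQK, link at Gln8)."""
    ctx = ctx or default_context()
    ions = fragments_crosslinked(db.by_id[SPECIES_1470], TRUE_CONTACT, ctx)
    return _spectrum(
        "fig3b_1470", _select_by_labels(ions, FIG3B_LABELS), DIMER_XL_FTICR[1]
    )


def fig3c_spectrum(
    db: SpeciesDatabase, ctx: ChemicalContext | None = None
) -> Tuple[float, PeakList]:
    """MS/MS of the 1998.02 precursor under its confirmed reading
    (QQpMAR x GSHMDKNELVQK with the link at Gln8 and Met1 unmodified)."""
    ctx = ctx or default_context()
    ions = fragments_crosslinked(db.by_id[SPECIES_1998_A], TRUE_CONTACT, ctx)
    return _spectrum(
        "fig3c_1998", _select_by_labels(ions, FIG3C_LABELS), DIMER_XL_FTICR[2]
    )


def fig4b_spectrum(
    db: SpeciesDatabase, ctx: ChemicalContext | None = None
) -> Tuple[float, PeakList]:
    """MS/MS of the 1881.85 monolink: a positional-isomer mixture (pMet22 +
    pMet26) over a common b-ion backbone."""
    ctx = ctx or default_context()
    sp = db.by_id[SPECIES_1881]
    ions: List[FragmentIon] = []
    for placement in sp.placements:
        ions.extend(fragments_peptide(sp.peptide_a, placement, ctx))
    masses = _select_by_labels(ions, FIG4B_ISOMER_LABELS + FIG4B_BSERIES_LABELS)
    return _spectrum("fig4b_1881", masses, MONOMER_SPECIES_FTICR[1])


def study_spectra(
    db: SpeciesDatabase, ctx: ChemicalContext | None = None
) -> List[Tuple[float, PeakList]]:
    """All reconstructed MS/MS spectra, keyed by precursor [M+H]+."""
    ctx = ctx or default_context()
    return [
        fig3a_spectrum(db, ctx),
        fig3b_spectrum(db, ctx),
        fig3c_spectrum(db, ctx),
        fig4b_spectrum(db, ctx),
    ]
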