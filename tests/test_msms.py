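"""Fragment generation, spectrum annotation, localization and isomer mixtures."""

import math
import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoxl.chem import default_context
from photoxl.digestion import ProteinSequence, digest
from photoxl.ms1_match import PeakList
from photoxl.msms import (
    annotate_spectrum,
    detect_isomer_mixture,
    fragments_crosslinked,
    fragments_linear,
    fragments_peptide,
    localize,
    read_msms_spectra,
)
from photoxl.study import (
    SPECIES_1342,
    SPECIES_1470,
    SPECIES_1881,
    SPECIES_1998_A,
    SPECIES_1998_B,
    fig3a_spectrum,
    fig3b_spectrum,
    fig3c_spectrum,
    fig4b_spectrum,
)

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=25)


def _nominal(ions, series, chain=None):
    return {
        ion.index: ion.nominal_mz
        for ion in ions
        if ion.series == series and (chain is None or ion.chain == chain)
    }


class TestLinearFragments:
    def test_nelvqk_b_series(self, ctx):
        b = _nominal(fragments_linear("NELVQK", ctx=ctx), "b")
        assert (b[2], b[3], b[4]) == (244, 357, 456)

    def test_terminated_pmet_y_series(self, ctx):
        term = ctx.modifications["pmet_terminated"]
        ions = fragments_linear("KQQMAR", [(4, term)], ctx)
        y = _nominal(ions, "y")
        assert (y[1], y[2]) == (175, 246)

    def test_dipeptide(self, ctx):
        ions = fragments_linear("GG", ctx=ctx)
        assert len([i for i in ions if i.series == "b"]) == 1
        assert len([i for i in ions if i.series == "y"]) == 1

    def test_too_short(self, ctx):
        with pytest.raises(ValueError):
            fragments_linear("G", ctx=ctx)

    @settings(derandomize=True, deadline=None)
    @given(seq=sequences)
    def test_by_complementarity(self, seq):
        # b_i + y_(n-i) = [M+H]+ + proton for every split point
        ctx = default_context()
        ions = fragments_linear(seq, ctx=ctx)
        b = {i.index: i.exact_mz for i in ions if i.series == "b"}
        y = {i.index: i.exact_mz for i in ions if i.series == "y"}
        mh = ctx.mz_singly_protonated(ctx.peptide_neutral_mass(seq))
        n = len(seq)
        for i in range(1, n):
            assert b[i] + y[n - i] == pytest.approx(mh + ctx.proton_mass, abs=1e-9)

    @settings(derandomize=True, deadline=None)
    @given(seq=sequences)
    def test_y_ladder_reconstructs_residues(self, seq):
        ctx = default_context()
        ions = fragments_linear(seq, ctx=ctx)
        y = {i.index: i.exact_mz for i in ions if i.series == "y"}
        # difference ladder gives residue masses from the C terminus inward
        prev = ctx.water_mass + ctx.proton_mass
        for i in range(1, len(seq)):
            residue = y[i] - prev
            assert residue == pytest.approx(
                ctx.residue_masses[seq[len(seq) - i]], abs=1e-9
            )
            prev = y[i]


class TestCrosslinkedFragments:
    def test_cleavage_ion_pair(self, ctx, db):
        ions = fragments_crosslinked(db.by_id[SPECIES_1342], (8, 78), ctx)
        alkene = next(i for i in ions if i.series == "xl_cleavage_alkene")
        restored = next(i for i in ions if i.series == "xl_cleavage_restored")
        assert alkene.nominal_mz == 613
        assert restored.exact_mz == pytest.approx(730.4094, abs=5e-4)

    def test_partner_carrying_y_series(self, ctx, db):
        ions = fragments_crosslinked(db.by_id[SPECIES_1470], (8, 78), ctx)
        y = _nominal(ions, "y", chain="a")
        assert [y[i] for i in (5, 4, 3, 2, 1)] == [1342, 1214, 1086, 246, 175]

    def test_y4_of_1342_precursor(self, ctx, db):
        ions = fragments_crosslinked(db.by_id[SPECIES_1342], (8, 78), ctx)
        y = _nominal(ions, "y", chain="a")
        assert y[4] == 1214

    def test_hypothesis_outside_chain_rejected(self, ctx, db):
        with pytest.raises(ValueError):
            fragments_crosslinked(db.by_id[SPECIES_1342], (50, 78), ctx)
        with pytest.raises(ValueError):
            fragments_crosslinked(db.by_id[SPECIES_1342], (8, 79), ctx)

    def test_cleavage_complementarity(self, ctx, db):
        # alkene + restored = precursor [M+H]+ + proton (the 613/730 pair)
        for sid in (SPECIES_1342, SPECIES_1470, SPECIES_1998_A):
            sp = db.by_id[sid]
            ions = fragments_crosslinked(sp, (8, 78), ctx)
            alkene = next(i for i in ions if i.series == "xl_cleavage_alkene")
            restored = next(i for i in ions if i.series == "xl_cleavage_restored")
            assert alkene.exact_mz + restored.exact_mz == pytest.approx(
                sp.mz(ctx) + ctx.proton_mass, abs=1e-6
            )

    def test_chain_complementarity_with_partner(self, ctx, db):
        sp = db.by_id[SPECIES_1342]
        ions = fragments_crosslinked(sp, (8, 78), ctx)
        mh = sp.mz(ctx)
        for chain, length in (("a", 5), ("b", 6)):
            b = {i.index: i.exact_mz for i in ions if i.series == "b" and i.chain == chain}
            y = {i.index: i.exact_mz for i in ions if i.series == "y" and i.chain == chain}
            for i in range(1, length):
                assert b[i] + y[length - i] == pytest.approx(
                    mh + ctx.proton_mass, abs=1e-9
                )


class TestAnnotate:
    def test_fig3a_fully_annotated(self, ctx, db):
        _, spec = fig3a_spectrum(db, ctx)
        ions = fragments_crosslinked(db.by_id[SPECIES_1342], (8, 78), ctx)
        res = annotate_spectrum(ions, spec, 0.5)
        assert len(res.matched) == len(spec)
        assert res.unmatched_observed == []

    def test_empty_observed(self, ctx, db):
        ions = fragments_crosslinked(db.by_id[SPECIES_1342], (8, 78), ctx)
        res = annotate_spectrum(ions, PeakList("e", peaks=()), 0.5)
        assert res.matched == []

    def test_tolerance_contract(self, ctx):
        ions = fragments_linear("NELVQK", ctx=ctx)
        b2 = next(i for i in ions if i.series == "b" and i.index == 2)
        shifted = PeakList("s", peaks=(b2.exact_mz + 0.4,))
        assert annotate_spectrum([b2], shifted, 0.5).matched
        assert not annotate_spectrum([b2], shifted, 0.3).matched

    def test_each_peak_used_once(self, ctx):
        ions = fragments_linear("NELVQK", ctx=ctx)
        b2 = next(i for i in ions if i.series == "b" and i.index == 2)
        res = annotate_spectrum([b2, b2], PeakList("s", peaks=(b2.exact_mz,)), 0.5)
        assert len(res.matched) == 1


class TestLocalize:
    def test_fig3a_confirms_gln8_met78(self, ctx, db):
        _, spec = fig3a_spectrum(db, ctx)
        res = localize(db.by_id[SPECIES_1342], spec)
        assert res.verdict == (8, 78)
        assert res.tier == "confirmed"

    def test_fig3b_confirms_gln8_met78(self, ctx, db):
        _, spec = fig3b_spectrum(db, ctx)
        res = localize(db.by_id[SPECIES_1470], spec)
        assert res.verdict == (8, 78)
        assert res.tier == "confirmed"

    def test_fig3c_resolves_dual_interpretation(self, ctx, db):
        _, spec = fig3c_spectrum(db, ctx)
        res = localize([db.by_id[SPECIES_1998_A], db.by_id[SPECIES_1998_B]], spec)
        assert res.verdict == (8, 78)
        assert res.tier == "confirmed"
        top = res.hypotheses[0]
        # every pMet1 reading is beaten: the unmodified b ions covering Met1
        # conflict with a cross-link on that chain
        for h in res.hypotheses:
            if h.pmet_site == 1:
                assert h.score < top.score
                assert h.conflicts > 0

    def test_co_elution_caps_tier_at_weak(self, ctx, db):
        _, spec = fig3c_spectrum(db, ctx)
        res = localize(
            [db.by_id[SPECIES_1998_A], db.by_id[SPECIES_1998_B]],
            spec,
            co_eluting=True,
        )
        assert res.verdict == (8, 78)
        assert res.tier == "weak"

    def test_no_site_determining_peaks_is_ambiguous(self, ctx, db):
        res = localize(db.by_id[SPECIES_1342], PeakList("e", peaks=()))
        assert res.verdict is None
        assert res.tier == "ambiguous"

    def test_monolink_rejected(self, ctx, db):
        with pytest.raises(ValueError):
            localize(db.by_id[SPECIES_1881], PeakList("e", peaks=()))


class TestIsomerMixture:
    def test_fig4b_mixture_at_22_and_26(self, ctx, db):
        _, spec = fig4b_spectrum(db, ctx)
        res = detect_isomer_mixture(db.by_id[SPECIES_1881], spec)
        assert res.status == "mixture"
        assert set(res.supported) == {(22,), (26,)}

    def test_single_placement(self, ctx, db):
        sp = db.by_id[SPECIES_1881]
        ions = fragments_peptide(sp.peptide_a, (22,), ctx)
        # exclusive evidence for pMet22 only: the y ions showing natural Met26
        y = {i.index: i.exact_mz for i in ions if i.series == "y"}
        spec = PeakList("s", peaks=(y[2], y[3], y[4]))
        res = detect_isomer_mixture(sp, spec)
        assert res.status == "single"
        assert res.supported == ((22,),)

    def test_no_evidence_undetermined(self, ctx, db):
        res = detect_isomer_mixture(db.by_id[SPECIES_1881], PeakList("e", peaks=()))
        assert res.status == "undetermined"

    def test_requires_alternative_placements(self, ctx, db):
        with pytest.raises(ValueError):
            detect_isomer_mixture(
                db.by_id["ML:12-27|k2"], PeakList("e", peaks=())
            )


class TestSpectrumIO:
    def test_mgf_roundtrip(self, tmp_path, ctx, db):
        _, spec = fig3a_spectrum(db, ctx)
        mgf = tmp_path / "spec.mgf"
        lines = ["BEGIN IONS", "TITLE=fig3a", "PEPMASS=1342.7457"]
        lines += [f"{mz:.4f} 100.0" for mz in spec.mz]
        lines += ["END IONS", ""]
        mgf.write_text("\n".join(lines))
        [(precursor, pl)] = read_msms_spectra(mgf)
        assert precursor == pytest.approx(1342.7457)
        assert len(pl) == len(spec)

    def test_tsv_fallback(self, tmp_path):
        p = tmp_path / "spec.tsv"
        p.write_text("100.5\t10\n200.25\n")
        [(precursor, pl)] = read_msms_spectra(p)
        assert precursor is None
        assert list(pl.mz) == [100.5, 200.25]
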