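"""Mass arithmetic: constants derived from elemental masses, peptide masses,
m/z conversion and ppm errors."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from photoxl.chem import ChemicalContext, default_context

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=RESIDUES, min_size=1, max_size=30)


class TestConstants:
    def test_residue_masses_match_elemental_formulas(self, ctx):
        # independent recomputation from pyteomics compositions
        for aa, comp in pmass.std_aa_comp.items():
            if len(aa) != 1 or not aa.isupper():
                continue
            expected = sum(
                pmass.nist_mass[el][0][0] * n for el, n in comp.items()
            )
            assert ctx.residue_masses[aa] == pytest.approx(expected, abs=1e-9)

    def test_proton_and_water(self, ctx):
        assert ctx.proton_mass == pytest.approx(1.007276, abs=1e-6)
        assert ctx.water_mass == pytest.approx(18.010565, abs=1e-6)

    def test_termination_shift_is_sulfur_for_carbon_swap(self, ctx):
        # Met residue (C5H9NOS) minus alkene termination product (C6H9NO)
        shift = ctx.formula_mass("C5H9NOS") - ctx.formula_mass("C6H9NO")
        assert shift == pytest.approx(ctx.pmet_termination_shift, abs=1e-12)
        assert round(shift, 3) == 19.972
        assert shift == pytest.approx(19.9721, abs=1e-4)

    @pytest.mark.parametrize(
        "mod_id,target,delta",
        [
            ("pmet_intact", "M", 8.0341),
            ("pmet_terminated", "M", -19.9721),
            ("pmet_inserted", "M", -19.9721),
            ("cam", "C", 57.0215),
            ("glycerol_adduct", "M", 92.0473),
            ("sodiated", "*", 21.9819),
        ],
    )
    def test_modification_registry(self, ctx, mod_id, target, delta):
        mod = ctx.modifications[mod_id]
        assert mod.target == target
        assert mod.delta_mass == pytest.approx(delta, abs=1e-4)

    def test_adducts_only_apply_on_photolysed_states(self, ctx):
        assert ctx.modifications["glycerol_adduct"].stackable_on == "pmet_inserted"
        assert ctx.modifications["sodiated"].stackable_on == "glycerol_adduct"


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [("NELVQK", 729.4021), ("G", 75.0320), ("QQMAR", 632.3064)],
    )
    def test_unmodified(self, ctx, seq, expected):
        assert ctx.peptide_neutral_mass(seq) == pytest.approx(expected, abs=5e-4)

    def test_agrees_with_pyteomics(self, ctx):
        # independent oracle: full composition-based calculation
        for seq in ("NELVQK", "QQMAR", "LAEQAERYDDMAACMK", "EMQPTHPIR"):
            assert ctx.peptide_neutral_mass(seq) == pytest.approx(
                pmass.calculate_mass(sequence=seq), abs=1e-9
            )

    def test_terminated_pmet_site(self, ctx):
        term = ctx.modifications["pmet_terminated"]
        got = ctx.peptide_neutral_mass("QQMAR", [(3, term)])
        assert got == pytest.approx(612.3344, abs=5e-4)
        assert got == pytest.approx(632.3064 - 19.9721, abs=5e-4)

    def test_errors(self, ctx):
        cam = ctx.modifications["cam"]
        with pytest.raises(ValueError):
            ctx.peptide_neutral_mass("")
        with pytest.raises(ValueError):
            ctx.peptide_neutral_mass("AXA")
        with pytest.raises(ValueError):
            ctx.peptide_neutral_mass("QQMAR", [(1, cam)])  # cam on Gln
        with pytest.raises(ValueError):
            ctx.peptide_neutral_mass("QQMAR", [(9, cam)])  # out of range

    @settings(derandomize=True, deadline=None)
    @given(a=sequences, b=sequences)
    def test_mass_additivity(self, a, b):
        ctx = default_context()
        whole = ctx.peptide_neutral_mass(a + b)
        parts = ctx.peptide_neutral_mass(a) + ctx.peptide_neutral_mass(b)
        assert whole == pytest.approx(parts - ctx.water_mass, abs=1e-6)


class TestMzAndPpm:
    def test_published_peptide_mz(self, ctx):
        # 159-167 tryptic peptide EMQPTHPIR
        neutral = ctx.peptide_neutral_mass("EMQPTHPIR")
        assert ctx.mz_singly_protonated(neutral) == pytest.approx(
            1108.5568, abs=1e-4
        )

    def test_protonation(self, ctx):
        assert ctx.mz_singly_protonated(729.4021) == pytest.approx(730.4094, abs=1e-4)
        with pytest.raises(ValueError):
            ctx.mz_singly_protonated(0.0)

    def test_ppm_examples(self, ctx):
        assert ctx.ppm_error(1500.0, 1500.0) == 0.0
        assert ctx.ppm_error(1342.7457, 1342.7437) == pytest.approx(1.49, abs=0.02)
        with pytest.raises(ValueError):
            ctx.ppm_error(-1.0, 100.0)

    def test_published_interlink_within_half_ppm(self, ctx):
        # GSHMDKNELVQK x QQpMAR interlink vs the printed 1998.0186
        theo = (
            ctx.peptide_neutral_mass("GSHMDKNELVQK")
            + ctx.peptide_neutral_mass("QQMAR")
            - ctx.pmet_termination_shift
            + ctx.proton_mass
        )
        assert abs(ctx.ppm_error(1998.0186, theo)) < 0.5

    @settings(derandomize=True, deadline=None)
    @given(
        obs=st.floats(100.0, 5000.0),
        theo=st.floats(100.0, 5000.0),
        delta=st.floats(0.0, 0.5),
    )
    def test_ppm_properties(self, obs, theo, delta):
        ctx = default_context()
        # antisymmetry up to the denominator change
        assert ctx.ppm_error(obs, theo) * ctx.ppm_error(theo, obs) <= 0
        # monotone in |observed - theoretical| at fixed theoretical
        near = abs(ctx.ppm_error(theo + delta, theo))
        far = abs(ctx.ppm_error(theo + delta + 0.1, theo))
        assert far > near
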