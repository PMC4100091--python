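"""Cross-link species enumeration and the searchable mass database."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from photoxl.chem import default_context
from photoxl.digestion import ProteinSequence, digest, met_sites
from photoxl.study import SPECIES_1998_A, SPECIES_1998_B
from photoxl.xl_candidates import (
    build_database,
    enumerate_interlinks,
    enumerate_monolinks,
    peptide_base_mass,
)


def _peptides(seq, max_missed=1, fixed_mods=("cam",)):
    return digest(
        ProteinSequence("p", seq, fixed_mods=fixed_mods),
        max_missed=max_missed,
        min_length=1,
    )


class TestInterlinks:
    def test_published_pair_masses(self, ctx, peptides):
        species = {
            s.id: s for s in enumerate_interlinks(peptides, ctx)
        }
        mz = species["IL:76-80|4-9|pM78"].mz(ctx)
        assert mz == pytest.approx(1342.7437, abs=5e-4)
        assert abs(ctx.ppm_error(1342.7457, mz)) < 2.0

    def test_no_met_no_interlink(self, ctx):
        peps = _peptides("NELVQK")
        assert enumerate_interlinks(peps, ctx) == []

    def test_dual_interpretation_equal_masses(self, ctx, db):
        a, b = db.by_id[SPECIES_1998_A], db.by_id[SPECIES_1998_B]
        assert a.neutral_mass == pytest.approx(b.neutral_mass, abs=1e-9)
        assert a.pmet_site == 78 and b.pmet_site == 1

    def test_mass_symmetric_in_chains(self, ctx, peptides):
        by_id = {s.id: s for s in enumerate_interlinks(peptides, ctx)}
        # swapped carrier/partner readings of the same peptide pair
        assert by_id["IL:76-80|-2-9|pM78"].neutral_mass == pytest.approx(
            by_id["IL:-2-9|76-80|pM1"].neutral_mass, abs=1e-12
        )

    def test_exhaustive_oracle_equivalence(self, ctx):
        # brute force over all peptide pairs of a small Met-rich protein
        seq = "MKAMCRGGMKLLNK"
        peps = _peptides(seq, max_missed=1)
        cam = ctx.modifications["cam"].delta_mass
        shift = ctx.pmet_termination_shift

        def oracle_mass(p):
            return pmass.calculate_mass(sequence=p.sequence) + cam * p.sequence.count("C")

        expected = []
        for p, q in itertools.combinations_with_replacement(peps, 2):
            pair_mass = oracle_mass(p) + oracle_mass(q) - shift
            n_species = (
                len(met_sites(p))
                if p is q
                else len(met_sites(p)) + len(met_sites(q))
            )
            expected.extend([pair_mass] * n_species)
        expected.sort()
        got = sorted(s.neutral_mass for s in enumerate_interlinks(peps, ctx))
        assert len(got) == len(expected)
        assert np.allclose(got, expected, atol=1e-9)


class TestMonolinks:
    @pytest.fixture()
    def species(self, ctx, peptides):
        adducts = [ctx.modifications["glycerol_adduct"], ctx.modifications["sodiated"]]
        return {s.id: s for s in enumerate_monolinks(peptides, adducts, ctx)}

    @pytest.mark.parametrize(
        "sid,printed",
        [
            ("ML:12-27|k1", 1881.8459),
            ("ML:12-27|k2", 1861.8735),
            ("AD:12-27|k1|glycerol_adduct+sodiated", 1995.8791),
        ],
    )
    def test_published_monomer_band_masses(self, ctx, species, sid, printed):
        assert abs(ctx.ppm_error(printed, species[sid].mz(ctx))) < 2.0

    def test_frozen_theoretical_values(self, ctx, species):
        assert species["ML:12-27|k1"].mz(ctx) == pytest.approx(1881.8469, abs=5e-4)
        assert species["ML:12-27|k2"].mz(ctx) == pytest.approx(1861.8749, abs=5e-4)

    def test_placements_collapse_to_one_mass_species(self, species):
        assert species["ML:12-27|k1"].placements == ((22,), (26,))
        assert species["ML:12-27|k2"].placements == ((22, 26),)

    def test_monolink_looplink_isobaric_exact(self, species):
        ml, ll = species["ML:12-27|k1"], species["LL:12-27|k1"]
        assert ml.neutral_mass == ll.neutral_mass  # identity, not approximation
        assert ll.id in ml.isobaric_with and ml.id in ll.isobaric_with

    def test_adduct_requires_photolysed_state(self, ctx, species):
        # adduct delta = glycerol + Na-for-H on top of the terminated form
        delta = (
            species["AD:12-27|k1|glycerol_adduct+sodiated"].neutral_mass
            - species["ML:12-27|k1"].neutral_mass
        )
        assert delta == pytest.approx(92.0473 + 21.9819, abs=1e-3)


class TestDatabase:
    def test_range_query_matches_linear_scan(self, ctx, db):
        rng = np.random.default_rng(7)
        masses = np.array([s.neutral_mass for s in db])
        for mass in rng.uniform(300, 3000, size=50):
            for tol in (0.5, 2.0, 40.0):
                got = {s.id for s in db.query_neutral(mass, tol)}
                lo, hi = mass / (1 + tol * 1e-6), mass / (1 - tol * 1e-6)
                expected = {
                    s.id for s, m in zip(db.species, masses) if lo <= m <= hi
                }
                assert got == expected

    def test_query_isobaric_pair_returned_together(self, ctx, db):
        hits = {s.id for s in db.query_mz(1881.8469, 0.5)}
        assert {"ML:12-27|k1", "LL:12-27|k1"} <= hits

    def test_full_database_1998_window(self, ctx, db):
        hits = {s.id for s in db.query_neutral(1997.011, 2.0)}
        assert hits == {SPECIES_1998_A, SPECIES_1998_B}

    def test_duplicate_ids_rejected(self, ctx, peptides):
        species = enumerate_interlinks(peptides[:10], ctx)
        if not species:
            pytest.skip("no interlinks in slice")
        with pytest.raises(ValueError, match="duplicate"):
            build_database(species + [species[0]], ctx)

    def test_empty_window(self, db):
        assert db.query_mz(50000.0, 2.0) == []


class TestPeptideBaseMass:
    def test_cam_applied_per_cysteine(self, ctx):
        peps = {p.sequence: p for p in _peptides("ACCK")}
        got = peptide_base_mass(peps["ACCK"], ctx)
        plain = ctx.peptide_neutral_mass("ACCK")
        assert got == pytest.approx(plain + 2 * 57.0215, abs=1e-3)
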