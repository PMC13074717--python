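"""Diversity descriptors, Hudson FST and neutrality statistics against
frozen fixture values and independently coded brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

import haplokit as hk
from util import (
    make_alignment,
    oracle_diversity,
    oracle_fu_li,
    oracle_pair_diff,
    oracle_tajima_d,
    random_alignment,
)


class TestPairwiseDifferences:
    def test_fixture_variant_classes_differ_at_both_indel_columns(
        self, fixture_table
    ):
        h2 = fixture_table.key_of("H2")
        h3 = fixture_table.key_of("H3")
        assert sum(a != b for a, b in zip(h2, h3)) == 2

    def test_identical_sequences(self):
        d = hk.pairwise_differences(make_alignment(["ACGT", "ACGT"]).records)
        assert d.tolist() == [[0, 0], [0, 0]]

    def test_gap_counts_as_one_difference(self):
        d = hk.pairwise_differences(make_alignment(["AC-T", "ACGT"]).records)
        assert d[0, 1] == 1

    def test_n_columns_excluded(self):
        d = hk.pairwise_differences(make_alignment(["NCGT", "ACGA"]).records)
        assert d[0, 1] == 1  # only column 3 counts

    def test_matches_naive_loop_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            aln = random_alignment(rng)
            d = hk.pairwise_differences(aln.records)
            seqs = [r.residues for r in aln.records]
            i, j = rng.choice(len(seqs), size=2, replace=False)
            assert d[i, j] == oracle_pair_diff(seqs[i], seqs[j])
            assert np.array_equal(d, d.T)
            assert np.all(np.diag(d) == 0)

    def test_length_mismatch(self):
        recs = [hk.SequenceRecord("a", "ACGT"), hk.SequenceRecord("b", "ACG")]
        with pytest.raises(ValueError, match="length mismatch"):
            hk.pairwise_differences(recs)


class TestDiversitySummary:
    def test_fixture_T(self, fixture_aln):
        s = hk.diversity_summary(fixture_aln, "T")
        assert (s.n, s.S, s.h) == (30, 1, 2)
        assert s.Hd == pytest.approx(1 / 15, abs=1e-12)
        assert f"{s.Hd:.3f}" == "0.067"
        assert s.pi == pytest.approx(29 / 435 / 594, abs=1e-12)
        assert f"{s.pi:.5f}" == "0.00011"

    def test_fixture_K_monomorphic(self, fixture_aln):
        s = hk.diversity_summary(fixture_aln, "K")
        assert (s.n, s.S, s.h, s.Hd, s.pi) == (16, 0, 1, 0.0, 0.0)
        assert s.mean_pairwise_diff == 0.0

    def test_fixture_Y_follows_the_formulas(self, fixture_aln):
        # printed summary values for this composition are inconsistent with
        # the printed class counts; the formulas win (see docs/methods.md)
        s = hk.diversity_summary(fixture_aln, "Y")
        assert (s.n, s.S, s.h) == (29, 2, 3)
        assert s.Hd == pytest.approx(332 / 812, abs=1e-12)
        assert s.mean_pairwise_diff == pytest.approx(178 / 406, abs=1e-12)
        assert s.pi == pytest.approx(178 / 406 / 594, abs=1e-12)

    def test_pi_bounded_by_S_over_L_and_Hd_in_unit_interval(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            aln = random_alignment(rng)
            s = hk.diversity_summary(aln, "P")
            assert 0 <= s.Hd <= 1
            assert s.pi <= s.S / s.L + 1e-12
            assert (s.Hd == 0) == (s.h == 1)
            assert (s.pi == 0) == (s.mean_pairwise_diff == 0) == (s.S == 0)

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            aln = random_alignment(rng, gap_prob=0.0)
            s = hk.diversity_summary(aln, "P")
            S, h, hd, pi, kbar = oracle_diversity([r.residues for r in aln])
            assert s.S == S and s.h == h
            assert s.Hd == pytest.approx(hd, abs=1e-9)
            assert s.pi == pytest.approx(pi, abs=1e-9)
            assert s.mean_pairwise_diff == pytest.approx(kbar, abs=1e-9)

    def test_kbar_equals_class_decomposition(self, fixture_aln, fixture_table):
        """k̄ from the haplotype-count decomposition equals the record-level
        mean (algebraic identity)."""
        for pop in fixture_aln.populations():
            n = fixture_aln.population_sizes()[pop]
            counts = {l: fixture_table.counts[pop].get(l, 0)
                      for l in fixture_table.labels}
            labels = [l for l in counts if counts[l] > 0]
            total = sum(
                counts[a] * counts[b]
                * sum(x != y for x, y in zip(fixture_table.key_of(a),
                                             fixture_table.key_of(b)))
                for i, a in enumerate(labels) for b in labels[i + 1:]
            )
            kbar = total / math.comb(n, 2)
            s = hk.diversity_summary(fixture_aln, pop)
            assert s.mean_pairwise_diff == pytest.approx(kbar, abs=1e-12)

    def test_singleton_population_rejected(self):
        aln = make_alignment(["ACGT", "ACGT"], ["A", "B"])
        with pytest.raises(ValueError, match="n=1 < 2"):
            hk.diversity_summary(aln, "A")


class TestHudsonFst:
    def test_fixture_T_K_is_exactly_zero(self, fixture_aln):
        r = hk.hudson_fst_pairwise(fixture_aln, "T", "K")
        assert r.hw_exact == r.hb_exact == Fraction(1, 30)
        assert r.fst == 0.0
        assert not r.degenerate

    def test_symmetry(self, fixture_aln):
        ab = hk.hudson_fst_pairwise(fixture_aln, "Y", "T")
        ba = hk.hudson_fst_pairwise(fixture_aln, "T", "Y")
        assert ab.hw_exact == ba.hw_exact and ab.hb_exact == ba.hb_exact

    def test_identical_compositions_show_only_small_sample_bias(self):
        """Two populations with the same polymorphic composition are
        undifferentiated up to the estimator's exact finite-sample bias
        -1/(n-1), which vanishes with n (identical monomorphic populations
        give 0 via the degenerate rule)."""
        for reps in (2, 5, 20):
            aln = make_alignment(
                ["AAAA", "AAAT"] * (2 * reps),
                (["P1"] * 2 + ["P2"] * 2) * reps,
            )
            r = hk.hudson_fst_pairwise(aln, "P1", "P2")
            n = 2 * reps
            assert r.fst == pytest.approx(-1 / (n - 1), abs=1e-12)
        mono = make_alignment(["ACGT"] * 8, ["P1"] * 4 + ["P2"] * 4)
        assert hk.hudson_fst_pairwise(mono, "P1", "P2").fst == 0.0

    def test_fixed_difference_gives_one(self):
        aln = make_alignment(
            ["AAAA", "AAAA", "AAAT", "AAAT"], ["P1", "P1", "P2", "P2"]
        )
        r = hk.hudson_fst_pairwise(aln, "P1", "P2")
        assert r.fst == 1.0
        assert r.hw_exact == 0 and r.hb_exact == 1

    def test_jointly_monomorphic_is_degenerate_zero(self):
        aln = make_alignment(["ACGT"] * 4, ["P1", "P1", "P2", "P2"])
        r = hk.hudson_fst_pairwise(aln, "P1", "P2")
        assert r.degenerate and r.fst == 0.0

    def test_fst_never_exceeds_one(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            spec = hk.random_population_spec(
                seed=int(rng.integers(0, 2**31 - 1)), n_pops=2, n_variants=3,
                backbone_length=60,
            )
            aln, _ = hk.generate_alignment(spec)
            sizes = aln.population_sizes()
            if min(sizes.values()) < 2:
                continue
            r = hk.hudson_fst_pairwise(aln, "P1", "P2")
            assert r.fst <= 1.0

    def test_overall_two_pops_equals_pairwise(self, fixture_aln):
        pair = hk.hudson_fst_pairwise(fixture_aln, "Y", "T")
        overall = hk.hudson_fst_overall(fixture_aln, ["Y", "T"])
        assert overall.hw_exact == pair.hw_exact
        assert overall.hb_exact == pair.hb_exact

    def test_overall_fixture_value(self, fixture_aln):
        """Unweighted three-population value from the fixture composition:
        exactly 107/1645 (~0.0650)."""
        r = hk.hudson_fst_overall(fixture_aln, ["Y", "T", "K"])
        assert Fraction(1) - r.hw_exact / r.hb_exact == Fraction(107, 1645)

    def test_overall_identical_monomorphic_pops_give_zero(self):
        aln = make_alignment(["ACGT"] * 6, ["P1", "P1", "P2", "P2", "P3", "P3"])
        r = hk.hudson_fst_overall(aln, ["P1", "P2", "P3"])
        assert r.fst == 0.0 and r.degenerate

    def test_overall_identical_polymorphic_pops_bias_shrinks_with_n(self):
        fst_small = hk.hudson_fst_overall(
            make_alignment(["AAAA", "AAAT"] * 6,
                           (["P1"] * 2 + ["P2"] * 2 + ["P3"] * 2) * 2),
            ["P1", "P2", "P3"],
        ).fst
        fst_large = hk.hudson_fst_overall(
            make_alignment(["AAAA", "AAAT"] * 30,
                           (["P1"] * 2 + ["P2"] * 2 + ["P3"] * 2) * 10),
            ["P1", "P2", "P3"],
        ).fst
        assert fst_small < fst_large < 0  # exact 0 only in the limit

    def test_requires_two_populations(self, fixture_aln):
        with pytest.raises(ValueError, match="at least 2"):
            hk.hudson_fst_overall(fixture_aln, ["Y"])


class TestNeutrality:
    def test_fixture_T_tajima(self, fixture_aln):
        r = hk.tajimas_d(fixture_aln, "T")
        assert r.tajima_d == pytest.approx(-1.147, abs=1e-3)
        assert r.constants["a1"] == pytest.approx(
            sum(1 / i for i in range(1, 30)), abs=1e-12
        )

    def test_fixture_T_fu_li_singleton_excess_is_negative(self, fixture_aln):
        r = hk.fu_li_star(fixture_aln, "T")
        assert (r.S, r.eta, r.eta_singletons) == (1, 1, 1)
        assert r.fu_li_d_star < 0 and r.fu_li_f_star < 0

    def test_no_polymorphism_gives_na(self, fixture_aln):
        taj = hk.tajimas_d(fixture_aln, "K")
        fl = hk.fu_li_star(fixture_aln, "K")
        assert taj.tajima_d is None
        assert fl.fu_li_d_star is None and fl.fu_li_f_star is None

    def test_minor_count_two_is_not_a_singleton(self):
        aln = make_alignment(["ACGT"] * 8 + ["ACGA"] * 2)
        r = hk.fu_li_star(aln, "P")
        assert r.eta == 1 and r.eta_singletons == 0

    def test_d_sign_follows_numerator(self):
        """D is zero exactly when k̄ = S/a1 and carries the numerator's sign."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            aln = random_alignment(rng)
            r = hk.tajimas_d(aln, "P")
            if r.tajima_d is None:
                continue
            kbar = hk.diversity_summary(aln, "P").mean_pairwise_diff
            numerator = kbar - r.S / r.constants["a1"]
            assert math.copysign(1, r.tajima_d) == math.copysign(1, numerator) \
                or abs(numerator) < 1e-12

    def test_matches_independent_oracle_on_random_alignments(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            aln = random_alignment(rng, gap_prob=0.2)
            seqs = [r.residues for r in aln]
            taj = hk.tajimas_d(aln, "P")
            fl = hk.fu_li_star(aln, "P")
            expected_d = oracle_tajima_d(seqs)
            expected_fl = oracle_fu_li(seqs)
            if expected_d is None:
                assert taj.tajima_d is None
                continue
            checked += 1
            assert taj.tajima_d == pytest.approx(expected_d, abs=1e-9)
            assert fl.fu_li_d_star == pytest.approx(expected_fl[0], abs=1e-9)
            assert fl.fu_li_f_star == pytest.approx(expected_fl[1], abs=1e-9)
        assert checked >= 50  # most draws are polymorphic

    def test_small_sample_rejected(self):
        aln = make_alignment(["ACGT", "ACGA", "ACGT"])
        with pytest.raises(ValueError, match="n >= 4"):
            hk.tajimas_d(aln, "P")
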