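"""Gapped PWM model: scoring, posterior, weighted estimation, similarity,
column moves."""

from __future__ import annotations

import math

import numpy as np
import pytest

from specmotif.pwm import (
    ColumnContext,
    GappedPWM,
    InstanceSet,
    Site,
    build_weighted_pwm,
    compareace_similarity,
    motif_prior,
    posterior_from_log_odds,
    sample_column_move,
    site_likelihood_ratio,
    site_posterior,
)
from specmotif.seqio import fit_markov_background


def one_hot_pwm(consensus: str) -> GappedPWM:
    f = np.zeros((len(consensus), 4))
    for j, c in enumerate(consensus):
        f[j, "ACGT".index(c)] = 1.0
    return GappedPWM(len(consensus), np.arange(len(consensus)), f, pseudocount=0.0)


class TestLikelihoodRatio:
    def test_all_A_site(self, uniform_bg):
        pwm = one_hot_pwm("AAA")
        L = site_likelihood_ratio(pwm, uniform_bg, "AAAA", 0, "+")
        assert L == pytest.approx((1 / 0.25) ** 3, rel=1e-9)

    def test_background_equal_frequencies_gives_unity(self, uniform_bg):
        f = np.full((4, 4), 0.25)
        pwm = GappedPWM(4, np.arange(4), f)
        for pos in range(5):
            L = site_likelihood_ratio(pwm, uniform_bg, "ACGTACGTA", pos, "+")
            assert L == pytest.approx(1.0, rel=1e-9)

    def test_zero_frequency_mismatch_gives_zero(self, uniform_bg):
        pwm = one_hot_pwm("AAA")
        assert site_likelihood_ratio(pwm, uniform_bg, "CAA", 0, "+") == 0.0

    def test_gap_columns_excluded(self, uniform_bg):
        # active columns 0 and 2 only; middle base must not matter
        f = np.zeros((2, 4))
        f[0, 0] = 1.0  # A
        f[1, 2] = 1.0  # G
        pwm = GappedPWM(3, np.array([0, 2]), f, pseudocount=0.0)
        for mid in "ACGT":
            L = site_likelihood_ratio(pwm, uniform_bg, f"A{mid}G", 0, "+")
            assert L == pytest.approx(16.0, rel=1e-9)

    def test_strand_flip_invariance(self, uniform_bg):
        # score of pwm on plus strand equals score of its reverse
        # complement on the minus strand at the same interval
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(4), size=5)
        pwm = GappedPWM(5, np.arange(5), f)
        seq = "ACGTTGCAGT"
        for pos in range(4):
            a = site_likelihood_ratio(pwm, uniform_bg, seq, pos, "+")
            b = site_likelihood_ratio(
                pwm.reverse_complement(), uniform_bg, seq, pos, "-"
            )
            assert a == pytest.approx(b, rel=1e-9)


class TestPriorAndPosterior:
    def test_prior_arithmetic(self):
        assert motif_prior(10, 5, 0.8, 1000) == pytest.approx(0.009)

    def test_prior_limits(self):
        assert motif_prior(10, 99, 1.0, 1000) == pytest.approx(10 / 1000)
        assert motif_prior(10, 99, 0.0, 1000) == pytest.approx(99 / 1000)

    def test_prior_requires_positive_T(self):
        with pytest.raises(ValueError):
            motif_prior(10, 5, 0.8, 0)

    def test_posterior_identity_at_L1(self):
        for p in (0.01, 0.5, 0.9):
            assert site_posterior(1.0, p) == pytest.approx(p, rel=1e-12)

    def test_posterior_arithmetic(self):
        assert site_posterior(3.0, 0.5) == pytest.approx(0.75)

    def test_posterior_limits(self):
        assert site_posterior(0.0, 0.5) == 0.0
        assert site_posterior(math.inf, 0.5) == 1.0

    def test_log_odds_form_agrees(self):
        for L, p in [(3.0, 0.5), (0.2, 0.1), (1e6, 0.001)]:
            assert posterior_from_log_odds(math.log(L), p) == pytest.approx(
                site_posterior(L, p), rel=1e-10
            )


def make_instances(strings, weights):
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.array([[enc[c] for c in s] for s in strings], dtype=np.int8)
    sites = [Site(i, 0, "+", 0.0) for i in range(len(strings))]
    return InstanceSet(sites=sites, base_matrix=mat, weights=np.asarray(weights, float))


class TestWeightedPWM:
    def test_equal_weights_equals_unweighted(self):
        inst = make_instances(["AA", "CC"], [1.0, 1.0])
        pwm = build_weighted_pwm(inst, 2, np.arange(2), pseudocount=0.0)
        assert np.allclose(pwm.freqs[:, 0], 0.5)
        assert np.allclose(pwm.freqs[:, 1], 0.5)

    def test_weighted_three_to_one(self):
        inst = make_instances(["A", "C"], [0.75, 0.25])
        pwm = build_weighted_pwm(inst, 1, np.arange(1), pseudocount=0.0)
        assert pwm.freqs[0, 0] == pytest.approx(0.75)
        assert pwm.freqs[0, 1] == pytest.approx(0.25)

    def test_uniform_weight_scaling_invariance(self):
        a = build_weighted_pwm(
            make_instances(["ACG", "AAG", "ACG"], [1.0, 1.0, 1.0]),
            3, np.arange(3), pseudocount=0.5,
        )
        b = build_weighted_pwm(
            make_instances(["ACG", "AAG", "ACG"], [0.2, 0.2, 0.2]),
            3, np.arange(3), pseudocount=0.5 * 0.2,
        )
        assert np.allclose(a.freqs, b.freqs)

    def test_instance_order_invariance(self):
        a = build_weighted_pwm(
            make_instances(["ACG", "TTG"], [0.9, 0.3]), 3, np.arange(3)
        )
        b = build_weighted_pwm(
            make_instances(["TTG", "ACG"], [0.3, 0.9]), 3, np.arange(3)
        )
        assert np.allclose(a.freqs, b.freqs)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            build_weighted_pwm(
                make_instances(["ACG"], [0.0]), 3, np.arange(3)
            )


class TestCompareACE:
    def test_identical_pwms(self, planted_pwm):
        assert compareace_similarity(planted_pwm, planted_pwm) == pytest.approx(1.0)

    def test_reverse_complement_match(self, planted_pwm):
        rc = planted_pwm.reverse_complement()
        assert compareace_similarity(planted_pwm, rc) == pytest.approx(1.0)

    def test_symmetry(self, planted_pwm, rng):
        other = GappedPWM(8, np.arange(8), rng.dirichlet(np.ones(4), size=8))
        assert compareace_similarity(planted_pwm, other) == pytest.approx(
            compareace_similarity(other, planted_pwm), abs=1e-12
        )

    def test_single_column_anticorrelation(self):
        a = one_hot_pwm("A")
        c = one_hot_pwm("C")
        assert compareace_similarity(a, c, min_overlap=1) == pytest.approx(-1 / 3)

    def test_offset_alignment_found(self, planted_pwm):
        # embed the planted pwm inside a wider matrix with uniform flanks
        wide = np.full((planted_pwm.window_width + 4, 4), 0.25)
        wide[2:-2] = planted_pwm.freqs
        w = GappedPWM(wide.shape[0], np.arange(wide.shape[0]), wide)
        assert compareace_similarity(planted_pwm, w) > 0.9


class TestColumnMoves:
    def _ctx(self, n, width, pad, rng):
        return ColumnContext(
            base_matrix=rng.integers(0, 4, size=(n, width + 2 * pad)).astype(np.int8),
            pad=pad,
            weights=np.ones(n),
        )

    def test_at_max_cols_only_removals(self, rng):
        pwm = GappedPWM(6, np.arange(6), np.full((6, 4), 0.25))
        ctx = self._ctx(5, 6, 2, rng)
        for _ in range(30):
            out = sample_column_move(pwm, ctx, rng, min_cols=2, max_cols=6,
                                     max_window=6, max_extend=2)
            assert out.width_w == 5  # always a removal

    def test_at_min_cols_only_additions(self, rng):
        pwm = GappedPWM(2, np.arange(2), np.full((2, 4), 0.25))
        ctx = self._ctx(5, 2, 2, rng)
        for _ in range(30):
            out = sample_column_move(pwm, ctx, rng, min_cols=2, max_cols=8,
                                     max_window=8, max_extend=2)
            assert out.width_w == 3  # always an addition

    def test_no_legal_move_returns_input(self, rng):
        pwm = GappedPWM(3, np.arange(3), np.full((3, 4), 0.25))
        ctx = self._ctx(5, 3, 0, rng)
        out = sample_column_move(pwm, ctx, rng, min_cols=3, max_cols=3,
                                 max_window=3, max_extend=0)
        assert out is pwm

    def test_move_type_proportions(self):
        rng = np.random.default_rng(123)
        # 12 active of window 18: both moves always legal
        active = np.sort(rng.choice(18, 12, replace=False))
        active[0], active[-1] = 0, 17
        active = np.unique(active)
        k = len(active)
        pwm = GappedPWM(18, active, np.full((k, 4), 0.25))
        ctx = self._ctx(5, 18, 3, rng)
        adds = 0
        trials = 4000
        for _ in range(trials):
            out = sample_column_move(pwm, ctx, rng, min_cols=4, max_cols=24,
                                     max_window=30, max_extend=3, p_add=0.5)
            adds += out.width_w > k
        assert abs(adds / trials - 0.5) < 0.03

    def test_flank_removal_shrinks_window(self):
        rng = np.random.default_rng(5)
        pwm = GappedPWM(4, np.array([0, 1, 3]), np.full((3, 4), 0.25))
        ctx = self._ctx(5, 4, 1, rng)
        seen_shrink = False
        for _ in range(50):
            out = sample_column_move(pwm, ctx, rng, min_cols=2, max_cols=3,
                                     max_window=4, max_extend=1)
            assert out.active[0] == 0
            assert out.active[-1] == out.window_width - 1
            if out.window_width < 4:
                seen_shrink = True
        assert seen_shrink


class TestInvariants:
    def test_anchored_window_invariant(self):
        with pytest.raises(ValueError):
            GappedPWM(5, np.array([1, 4]), np.full((2, 4), 0.25))

    def test_row_normalization_checked(self):
        f = np.full((3, 4), 0.3)
        with pytest.raises(ValueError):
            GappedPWM(3, np.arange(3), f)

    def test_symmetric_kl_zero_on_self(self, planted_pwm):
        assert planted_pwm.symmetric_kl(planted_pwm) == 0.0

    def test_symmetric_kl_inf_on_geometry_change(self, planted_pwm):
        other = GappedPWM(4, np.arange(4), np.full((4, 4), 0.25))
        assert planted_pwm.symmetric_kl(other) == math.inf
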