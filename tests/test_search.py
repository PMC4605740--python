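"""Search engine: restarts, threshold optimization, archive, cache."""

from __future__ import annotations

import math

import numpy as np
import pytest

from specmotif.pwm import GappedPWM
from specmotif.search import (
    BestSiteCache,
    MotifArchive,
    MotifModel,
    SearchEngine,
    SearchParams,
    num_restarts,
    optimize_threshold_grid,
    run_search,
)
from specmotif.seqio import fit_markov_background
from specmotif.specificity import SpecificityContext, specificity_score
from specmotif.synth import _random_motif


class TestNumRestarts:
    def test_arithmetic(self):
        assert num_restarts(30000, 12, 10) == 250

    def test_floor_guard(self):
        assert num_restarts(50, 12, 10) == 1

    def test_doubling_k_halves(self):
        assert num_restarts(24000, 12, 10) == 2 * num_restarts(24000, 12, 20)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            num_restarts(0, 12, 10)


def brute_force_thresholds(b, post):
    """Independent oracle: enumerate every candidate threshold pair."""
    N = len(b)
    best = None
    for bt in sorted(set(b[np.isfinite(b)]), reverse=True):
        for st in sorted(set(post), reverse=True):
            s1m = b >= bt
            s2m = post >= st
            ctx = SpecificityContext(
                N, int(s1m.sum()), int(s2m.sum()), int((s1m & s2m).sum())
            )
            sc = specificity_score(ctx)
            key = (sc, ctx.s1, ctx.s2)
            if best is None or key > best[0]:
                best = (key, bt, st, ctx)
    return best


class TestOptimizeThresholdGrid:
    def test_separable_case(self):
        # exactly the motif-bearing sequences have binding score 1
        b = np.array([1.0] * 5 + [0.0] * 15)
        post = np.array([0.9] * 5 + [0.1] * 15)
        bt, st, ctx, score = optimize_threshold_grid(b, post)
        assert (ctx.s1, ctx.s2, ctx.x) == (5, 5, 5)
        assert bt == 1.0 and st == 0.9

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for trial in range(40):
            N = int(rng.integers(5, 60))
            b = np.round(rng.random(N), 2)
            post = np.round(rng.random(N), 2)
            bt, st, ctx, score = optimize_threshold_grid(b, post)
            (bkey, bbt, bst, bctx) = brute_force_thresholds(b, post)
            assert score == pytest.approx(bkey[0], abs=1e-9)
            assert (ctx.s1, ctx.s2, ctx.x) == (bctx.s1, bctx.s2, bctx.x)

    def test_unscored_sequences_stay_out_of_s1(self):
        b = np.array([2.0, 1.0, -math.inf, -math.inf])
        post = np.array([0.9, 0.8, 0.95, 0.1])
        bt, st, ctx, score = optimize_threshold_grid(b, post)
        assert ctx.s1 <= 2
        # but they count toward N and can be in s2
        assert ctx.N == 4

    def test_irrelevant_sequence_leaves_optimum(self):
        b = np.array([1.0] * 4 + [0.0] * 8)
        post = np.array([0.9] * 4 + [0.1] * 8)
        bt1, st1, ctx1, s1 = optimize_threshold_grid(b, post)
        b2 = np.append(b, -1.0)  # below every candidate, no motif
        post2 = np.append(post, 0.0)
        bt2, st2, ctx2, s2 = optimize_threshold_grid(b2, post2)
        assert (ctx2.s1, ctx2.s2, ctx2.x) == (ctx1.s1, ctx1.s2, ctx1.x)
        assert ctx2.N == ctx1.N + 1


def _model(score, consensus, x=10):
    f = np.zeros((len(consensus), 4))
    for j, c in enumerate(consensus):
        f[j] = 0.04
        f[j, "ACGT".index(c)] = 0.88
    pwm = GappedPWM(len(consensus), np.arange(len(consensus)), f / f.sum(1, keepdims=True))
    return MotifModel(pwm=pwm, binding_threshold=0.0, site_threshold=0.5,
                      ctx=SpecificityContext(100, 30, 20, x), score=score)


class TestMotifArchive:
    def test_empty_archive_inserts(self):
        a = MotifArchive(0.9)
        assert a.add(_model(5.0, "ACGTACGTAA"))
        assert len(a) == 1

    def test_duplicate_of_better_rejected(self):
        a = MotifArchive(0.9)
        a.add(_model(9.0, "ACGTACGTAA"))
        assert not a.add(_model(5.0, "ACGTACGTAA"))
        assert len(a) == 1

    def test_better_duplicate_evicts(self):
        a = MotifArchive(0.9)
        a.add(_model(5.0, "ACGTACGTAA"))
        assert a.add(_model(9.0, "ACGTACGTAA"))
        assert len(a) == 1 and a.best.score == 9.0

    def test_insertion_order_invariance(self):
        models = [
            _model(3.0, "ACGTACGTAA"),
            _model(7.0, "ACGTACGTAA"),  # redundant with above
            _model(5.0, "TTTTCCCCGG"),
            _model(9.0, "GGGCCATATA"),
        ]
        import itertools

        outcomes = set()
        for perm in itertools.permutations(models):
            a = MotifArchive(0.9)
            for m in perm:
                a.add(m)
            outcomes.add(tuple(round(m.score, 6) for m in a))
        assert outcomes == {(9.0, 7.0, 5.0)}

    def test_sorted_descending(self):
        a = MotifArchive(0.9)
        for m in [_model(2.0, "AAAACGTTTT"), _model(8.0, "GGGGCATACA"),
                  _model(5.0, "TTACGTGCAA")]:
            a.add(m)
        scores = [m.score for m in a]
        assert scores == sorted(scores, reverse=True)


class TestSeedAndDeterminism:
    def test_seed_model_deterministic(self, chip_fixture):
        ds, _ = chip_fixture
        bg = fit_markov_background(ds, 2)
        eng = SearchEngine(ds, bg, SearchParams(seed=3))
        m1 = eng.seed_model(np.random.default_rng(77))
        m2 = eng.seed_model(np.random.default_rng(77))
        assert np.allclose(m1.pwm.freqs, m2.pwm.freqs)
        assert m1.binding_threshold == m2.binding_threshold

    def test_seed_pwm_argmax_spells_site(self, chip_fixture):
        ds, _ = chip_fixture
        bg = fit_markov_background(ds, 2)
        eng = SearchEngine(ds, bg, SearchParams(seed=3))
        m = eng.seed_model(np.random.default_rng(5))
        site = m.instances.sites[0]
        seq = ds[site.seq_index].bases
        window = seq[site.pos : site.pos + m.pwm.window_width]
        if site.strand == "-":
            from specmotif.seqio import revcomp

            window = revcomp(window)
        assert m.pwm.consensus == window

    def test_single_sequence_search_space_rejected(self):
        from specmotif.seqio import Dataset, ScoredSequence

        ds = Dataset([
            ScoredSequence("a", "ACGTACGTACGTACGT", binding_score=5.0),
            ScoredSequence("b", "ACGTACGTACGTACGT", binding_score=-1000.0),
        ])
        bg = fit_markov_background(ds, 0)
        eng = SearchEngine(ds, bg, SearchParams(seed=1))
        b = np.array([5.0, -1000.0])
        # median threshold keeps both; force an empty space via scores
        with pytest.raises(ValueError):
            eng.seed_model(np.random.default_rng(0), b=np.array([5.0, np.nan]))


class TestBestSiteCache:
    def test_cache_hit_on_unchanged_pwm(self, chip_fixture):
        ds, truth = chip_fixture
        bg = fit_markov_background(ds, 2)
        eng = SearchEngine(ds, bg, SearchParams(seed=0))
        pwm = truth.functional[0].pwm
        cache = BestSiteCache()
        lo1, pos1, st1, used1 = eng.ws.best_sites(pwm, cache, 0.5)
        assert not used1
        lo2, pos2, st2, used2 = eng.ws.best_sites(pwm, cache, 0.5)
        assert used2
        assert np.array_equal(lo1, lo2)
        assert np.array_equal(pos1, pos2)
        assert np.array_equal(st1, st2)

    def test_full_scan_on_big_change(self, chip_fixture, rng):
        ds, truth = chip_fixture
        bg = fit_markov_background(ds, 2)
        eng = SearchEngine(ds, bg, SearchParams(seed=0))
        pwm = truth.functional[0].pwm
        cache = BestSiteCache()
        eng.ws.best_sites(pwm, cache, 0.5)
        other = _random_motif(np.random.default_rng(9), 10, 2)
        _, _, _, used = eng.ws.best_sites(other, cache, 0.5)
        assert not used  # KL way beyond trigger

    def test_geometry_change_forces_full_scan(self, chip_fixture):
        ds, truth = chip_fixture
        bg = fit_markov_background(ds, 2)
        eng = SearchEngine(ds, bg, SearchParams(seed=0))
        pwm = truth.functional[0].pwm
        cache = BestSiteCache()
        eng.ws.best_sites(pwm, cache, 0.5)
        gapped = GappedPWM(
            pwm.window_width,
            np.concatenate([pwm.active[:4], pwm.active[5:]]),
            np.vstack([pwm.freqs[:4], pwm.freqs[5:]]),
        )
        _, _, _, used = eng.ws.best_sites(gapped, cache, 0.5)
        assert not used


class TestRunSearchSmoke:
    def test_recovers_planted_motif(self, chip_fixture, planted_pwm):
        from specmotif.pwm import compareace_similarity

        ds, _ = chip_fixture
        bg = fit_markov_background(ds, 2)
        params = SearchParams(seed=4, minpass=5, max_restarts=8, max_phases=8,
                              wave_size=4)
        archive = run_search(ds, bg, params)
        assert len(archive) > 0
        assert compareace_similarity(archive.best.pwm, planted_pwm) >= 0.75

    def test_same_seed_same_archive(self, chip_fixture):
        ds, _ = chip_fixture
        bg = fit_markov_background(ds, 2)
        params = SearchParams(seed=9, minpass=4, max_restarts=4, max_phases=6)
        a1 = run_search(ds, bg, params)
        a2 = run_search(ds, bg, params)
        assert [m.score for m in a1] == [m.score for m in a2]
        for m1, m2 in zip(a1, a2):
            assert np.allclose(m1.pwm.freqs, m2.pwm.freqs)
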