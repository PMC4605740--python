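"""The motif search engine.

A search alternates two loops.  The inner loop iteratively refines a motif
model seeded from a single random site: scan for each sequence's best site,
admit sequences whose best-site posterior clears the sequence-score
threshold, and rebuild the weighted PWM from the admitted sites (optionally
proposing a column add/remove).  When ``minpass`` consecutive iterations
bring no improvement in the specificity score, the outer loop re-optimizes
the two dynamic thresholds (binding-score threshold defining the search
space, and sequence-score threshold defining instances) exactly over the
observed-value grid, and refinement resumes; the restart ends when a
threshold step yields no further improvement.  Restarts are independent
given per-restart seeds and feed a non-redundant, score-sorted motif
archive; a restart is abandoned early when its current PWM matches an
archived higher-scoring motif.

Performance comes from two heuristics: a best-site cache that rescans only
the top-K sites per sequence from the last full scan while the PWM has not
changed much, and deterministic fixed-size restart waves that can be spread
over worker threads without changing the result.
"""

from __future__ import annotations

import copy
import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .pwm import (
    ColumnContext,
    GappedPWM,
    InstanceSet,
    Site,
    build_weighted_pwm,
    compareace_similarity,
    motif_prior,
    posterior_from_log_odds,
    sample_column_move,
)
from .seqio import Dataset, MarkovBackground, encode
from .specificity import SpecificityContext, specificity_score

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "MotifModel",
    "MotifArchive",
    "BestSiteCache",
    "ScanWorkspace",
    "SearchEngine",
    "num_restarts",
    "run_search",
    "optimize_threshold_grid",
]

_TOL = 1e-9


def num_restarts(s1_bp: int, width_w: int, sampling_k: int) -> int:
    """Number of random restarts: s1_bp / (w k), at least one.

    s1_bp is the search-space size in base pairs, w the number of PWM
    columns, k the sampling parameter controlling search thoroughness.
    """
    if s1_bp <= 0 or width_w <= 0 or sampling_k <= 0:
        raise ValueError("all arguments must be positive")
    return max(1, s1_bp // (width_w * sampling_k))


@dataclass
class SearchParams:
    """Tunable knobs of the search.  Defaults follow the common AlignACE
    lineage settings; geometry bounds constrain the gapped-PWM column moves."""

    minpass: int = 50
    prior_weight_w: float = 0.8
    sampling_k: int = 10
    redundancy_threshold: float = 0.9
    seed: int = 0
    window_init: int = 12
    min_cols: int = 6
    max_cols: int = 24
    max_window: int = 30
    max_extend: int = 3
    move_prob: float = 0.25
    p_add: float = 0.5
    pseudocount: float = 0.5
    site_threshold_init: float = 0.5
    rescan_kl: float = 0.5
    cache_topk: int = 8
    check_interval: int = 10
    grid_max: int = 256
    workers: int = 1
    wave_size: int = 8
    max_restarts: int | None = None
    max_archive: int = 150
    max_phases: int = 10
    max_iters_per_phase: int = 400
    early_abandon_iter: int | None = None
    early_abandon_score: float = 0.0
    polish: bool = True
    polish_max: int = 120
    polish_minpass: int = 3

    def __post_init__(self) -> None:
        if self.minpass < 1:
            raise ValueError("minpass must be >= 1")
        if not (0 < self.redundancy_threshold <= 1):
            raise ValueError("redundancy threshold must be in (0, 1]")


@dataclass
class MotifModel:
    """A motif model: gapped PWM plus the two dynamic thresholds, with the
    bookkeeping of the counts they induce."""

    pwm: GappedPWM
    binding_threshold: float
    site_threshold: float
    instances: InstanceSet | None = None
    ctx: SpecificityContext | None = None
    score: float = -math.inf
    member_indices: np.ndarray | None = None  # the x-set (s1 & s2)
    dead: bool = False

    @property
    def consensus(self) -> str:
        return self.pwm.consensus


class MotifArchive:
    """Score-sorted, non-redundant motif collection.

    A model is inserted only when no archived motif with a score at least as
    high is similar to it (CompareACE above the redundancy threshold); on
    insertion, lower-scoring redundant members are evicted.  Ties in score
    break toward larger x, then lexicographic consensus, which makes the
    final archive independent of insertion order for distinct scores.
    """

    def __init__(self, redundancy_threshold: float = 0.9, max_size: int | None = None):
        self.redundancy_threshold = redundancy_threshold
        self.max_size = max_size
        self.models: list[MotifModel] = []

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @staticmethod
    def _key(m: MotifModel):
        x = m.ctx.x if m.ctx else 0
        return (-m.score, -x, m.consensus)

    def add(self, model: MotifModel) -> bool:
        """archive_add: insert iff not redundant with an equal-or-higher
        scoring member; evict redundant lower-scoring members.  Returns the
        insertion flag."""
        thr = self.redundancy_threshold
        kept = []
        for m in self.models:
            sim = compareace_similarity(m.pwm, model.pwm)
            if sim > thr:
                if self._key(m) <= self._key(model):
                    return False  # an equal-or-better similar motif exists
                continue  # evict the worse redundant member
            kept.append(m)
        kept.append(model)
        kept.sort(key=self._key)
        if self.max_size is not None:
            kept = kept[: self.max_size]
        self.models = kept
        return True

    def snapshot(self) -> list[MotifModel]:
        return list(self.models)

    @property
    def best(self) -> MotifModel | None:
        return self.models[0] if self.models else None


def archive_add(archive: MotifArchive, model: MotifModel,
                redundancy_threshold: float | None = None) -> bool:
    if redundancy_threshold is not None:
        archive.redundancy_threshold = redundancy_threshold
    return archive.add(model)


@dataclass
class BestSiteCache:
    """Top-K candidate sites per sequence from the last full scan, plus the
    PWM they were computed under.  The cache path rescans only these
    candidates; any geometry change or a symmetric-KL drift beyond the
    rescan trigger forces a full scan."""

    cand_pos: np.ndarray | None = None
    cand_str: np.ndarray | None = None
    ref_pwm: GappedPWM | None = None

    @property
    def valid(self) -> bool:
        return self.cand_pos is not None

    def update(self, cand_pos, cand_str, pwm) -> None:
        self.cand_pos = cand_pos
        self.cand_str = cand_str
        self.ref_pwm = pwm

    def invalidate(self) -> None:
        self.cand_pos = None
        self.cand_str = None
        self.ref_pwm = None


class ScanWorkspace:
    """Padded encoded sequences plus per-position background log-probs,
    shared by every scan of a search run."""

    def __init__(self, dataset: Dataset, bg: MarkovBackground):
        self.dataset = dataset
        self.bg = bg
        self.lengths = dataset.lengths().astype(np.int64)
        N = len(dataset)
        L = int(self.lengths.max()) if N else 0
        self.E = np.full((N, L), 4, dtype=np.int8)
        for i, s in enumerate(dataset):
            self.E[i, : len(s)] = encode(s.bases)
        logflat, offs = bg.flat_log_tables()
        self.Bp, self.Bm = _kernels.position_bg_logprobs(
            self.E, self.lengths, logflat, offs, bg.order
        )
        # prefix sums of the largest -B over context levels (0 at N
        # positions), a valid upper bound for the scan pruning
        negp = np.where(self.E < 4, (-self.Bp).max(axis=0), 0.0)
        negm = np.where(self.E < 4, (-self.Bm).max(axis=0), 0.0)
        self.CBp = np.concatenate(
            [np.zeros((N, 1)), np.cumsum(negp, axis=1, dtype=np.float64)], axis=1
        )
        self.CBm = np.concatenate(
            [np.zeros((N, 1)), np.cumsum(negm, axis=1, dtype=np.float64)], axis=1
        )

    @property
    def N(self) -> int:
        return self.E.shape[0]

    def total_positions(self, width: int, mask: np.ndarray | None = None) -> int:
        lens = self.lengths if mask is None else self.lengths[mask]
        return int((2 * np.maximum(0, lens - width + 1)).sum())

    @staticmethod
    def _window_logf(pwm: GappedPWM) -> np.ndarray:
        logf = np.full((pwm.window_width, 4), 0.0)
        with np.errstate(divide="ignore"):
            logf[pwm.active] = np.log(pwm.freqs)
        return logf

    def _levels(self, pwm: GappedPWM) -> np.ndarray:
        return np.minimum(self.bg.order, pwm.active).astype(np.int64)

    def full_scan(self, pwm: GappedPWM, topk: int = 8):
        cand_lo, cand_pos, cand_str = _kernels.full_scan_topk(
            self.E, self.Bp, self.Bm, self.CBp, self.CBm, self.lengths,
            self._window_logf(pwm), pwm.active, self._levels(pwm),
            pwm.window_width, topk,
        )
        return (
            cand_lo[:, 0].copy(), cand_pos[:, 0].copy(), cand_str[:, 0].copy(),
            cand_pos, cand_str,
        )

    def rescan(self, pwm: GappedPWM, cand_pos, cand_str):
        return _kernels.rescan_candidates(
            self.E, self.Bp, self.Bm, self.lengths, cand_pos, cand_str,
            self._window_logf(pwm), pwm.active, self._levels(pwm),
            pwm.window_width,
        )

    def best_sites(self, pwm: GappedPWM, cache: BestSiteCache,
                   rescan_kl: float, topk: int = 8, force_full: bool = False):
        """Per-sequence best site, via the cache when the PWM is close to the
        one the cache was built under.  Returns (lo, pos, strand, used_cache)."""
        if (
            not force_full
            and cache.valid
            and pwm.symmetric_kl(cache.ref_pwm) <= rescan_kl
        ):
            lo, pos, st = self.rescan(pwm, cache.cand_pos, cache.cand_str)
            return lo, pos, st, True
        lo, pos, st, cp, cs = self.full_scan(pwm, topk)
        cache.update(cp, cs, pwm)
        return lo, pos, st, False

    def extract_windows(self, idx: np.ndarray, pos: np.ndarray,
                        strand: np.ndarray, width: int, pad: int = 0) -> np.ndarray:
        """Site windows (plus ``pad`` flanks) oriented 5'->3'; positions
        beyond the sequence are marked 4."""
        n = len(idx)
        out = np.full((n, width + 2 * pad), 4, dtype=np.int8)
        for r in range(n):
            i = int(idx[r])
            p = int(pos[r])
            M = int(self.lengths[i])
            lo = max(0, p - pad)
            hi = min(M, p + width + pad)
            seg = self.E[i, lo:hi]
            out[r, lo - (p - pad) : hi - (p - pad)] = seg
            if strand[r] == 1:
                row = out[r, ::-1].copy()
                valid = row < 4
                row[valid] = 3 - row[valid]
                out[r] = row
        return out


def _quantile_thin(values: np.ndarray, max_n: int) -> np.ndarray:
    """Unique candidate cut values, descending; thinned to at most ``max_n``
    quantile-spaced values (always keeping the extremes) when there are more."""
    u = np.unique(values)[::-1]
    if len(u) <= max_n:
        return u
    take = np.unique(np.linspace(0, len(u) - 1, max_n).round().astype(int))
    return u[take]


def optimize_threshold_grid(
    binding_scores: np.ndarray,
    posteriors: np.ndarray,
    grid_max: int = 256,
):
    """Exact maximizer of the specificity score over the candidate grid
    {observed binding scores} x {observed best-site posteriors}.

    Thresholds are '>=' cuts.  Computed by a cumulative 2-D count sweep; ties
    break toward larger s1, then larger s2 (the more inclusive model).  With
    more than ``grid_max`` distinct values on an axis the grid is thinned to
    quantile-spaced cuts (exact below that).  Returns
    (binding_threshold, site_threshold, SpecificityContext, score).
    """
    b = np.asarray(binding_scores, dtype=np.float64)
    p = np.asarray(posteriors, dtype=np.float64)
    N = len(b)
    bc = _quantile_thin(b[np.isfinite(b)] if np.isfinite(b).any() else np.array([0.0]),
                        grid_max)
    pc = _quantile_thin(p, grid_max)
    nb, npc = len(bc), len(pc)
    # index of the first (largest) cut each sequence satisfies
    ib = np.searchsorted(-bc, -b, side="left")  # b >= bc[j] for j >= ib
    ip = np.searchsorted(-pc, -p, side="left")
    hist = np.zeros((nb + 1, npc + 1), dtype=np.int64)
    np.add.at(hist, (ib, ip), 1)
    X = hist[:-1, :-1].copy()
    np.cumsum(X, axis=0, out=X)
    np.cumsum(X, axis=1, out=X)
    s1 = X[:, -1]
    # s2 counts over all N sequences, including those (e.g. unscored, binding
    # score -inf) that can never enter the search space
    s2 = np.cumsum(hist.sum(axis=0)[:-1])
    s1g = np.broadcast_to(s1[:, None], X.shape).ravel().astype(np.int64)
    s2g = np.broadcast_to(s2[None, :], X.shape).ravel().astype(np.int64)
    xg = X.ravel().astype(np.int64)
    scores = _kernels.spec_scores_vec(np.int64(N), s1g, s2g, xg)
    flat = np.lexsort((s2g, s1g, scores))[-1]
    i, j = divmod(int(flat), npc)
    ctx = SpecificityContext(N=N, s1=int(s1[i]), s2=int(s2[j]), x=int(X[i, j]))
    return float(bc[i]), float(pc[j]), ctx, float(scores[flat])


@dataclass
class _RestartResult:
    model: MotifModel | None
    iterations: int
    reason: str


class SearchEngine:
    """Binds a dataset, background model and parameters, and runs restarts.

    ``dynamics`` customizes the binding-score axis per iteration (the
    expression mode supplies an object that recomputes correlation scores
    from an evolving profile); when None, binding scores are the static
    per-sequence scores of the dataset.
    """

    def __init__(self, dataset: Dataset, bg: MarkovBackground,
                 params: SearchParams, dynamics=None):
        self.dataset = dataset
        self.bg = bg
        self.params = params
        self.dynamics = dynamics
        self.ws = ScanWorkspace(dataset, bg)
        self.static_b = dataset.binding_scores()
        self.static_w = dataset.normalized_scores()

    # -- seeding ----------------------------------------------------------

    def seed_model(self, rng: np.random.Generator, b: np.ndarray | None = None,
                   seed_seq: int | None = None) -> MotifModel:
        """Initialize a model from one random site of the positive search
        space: a one-hot PWM built from the site's bases, the binding
        threshold at the median observed score (start broad), and the site
        threshold at its default posterior."""
        p = self.params
        if b is None:
            b = self.static_b
        fin = b[np.isfinite(b)]
        if fin.size == 0:
            raise ValueError("no finite binding scores: empty search space")
        bt = float(np.median(fin))
        s1_mask = b >= bt
        if s1_mask.sum() < 2:
            raise ValueError("search space has fewer than 2 sequences")
        W = p.window_init
        lens = self.ws.lengths
        npos = np.where(s1_mask, np.maximum(0, lens - W + 1), 0)
        if seed_seq is None:
            if npos.sum() == 0:
                raise ValueError("no scannable positions in the search space")
            probs = npos / npos.sum()
            seed_seq = int(rng.choice(len(probs), p=probs))
        if npos[seed_seq] <= 0:
            raise ValueError("seed sequence too short for the window")
        for _ in range(200):
            pos = int(rng.integers(npos[seed_seq]))
            strand = int(rng.integers(2))
            window = self.ws.extract_windows(
                np.array([seed_seq]), np.array([pos]), np.array([strand]), W
            )[0]
            if (window < 4).all():
                break
        else:
            raise ValueError("could not find an N-free seed window")
        inst = InstanceSet(
            sites=[Site(seed_seq, pos, "-" if strand else "+", 0.0)],
            base_matrix=window[None, :],
            weights=np.array([1.0]),
        )
        pwm = build_weighted_pwm(
            inst, W, np.arange(W), p.pseudocount, self.bg.marginals
        )
        return MotifModel(
            pwm=pwm,
            binding_threshold=bt,
            site_threshold=p.site_threshold_init,
            instances=inst,
        )

    # -- one refinement iteration -----------------------------------------

    def _score_pwm(self, pwm: GappedPWM, b: np.ndarray, bt: float, st: float,
                   x_prev: int, cache: BestSiteCache | None = None):
        """Specificity of ``pwm`` under fixed thresholds.

        When a populated cache is supplied, the score is evaluated over the
        cached candidate sites (cheap, used to compare column-move
        proposals on an equal footing); otherwise a full scan is used.
        """
        s1_mask = b >= bt
        s1 = int(s1_mask.sum())
        T = self.ws.total_positions(pwm.window_width, s1_mask)
        if s1 < 2 or T <= 0:
            return -math.inf, None
        prior = motif_prior(s1, x_prev, self.params.prior_weight_w, T)
        if cache is not None and cache.valid:
            lo, pos, _ = self.ws.rescan(pwm, cache.cand_pos, cache.cand_str)
            lo = np.where(pos >= 0, lo, -np.inf)
        else:
            lo, _, _, _, _ = self.ws.full_scan(pwm, 1)
        post = posterior_from_log_odds(lo, prior)
        s2_mask = post >= st
        x = int((s1_mask & s2_mask).sum())
        ctx = SpecificityContext(N=self.ws.N, s1=s1, s2=int(s2_mask.sum()), x=x)
        return specificity_score(ctx), ctx

    def refine_iteration(
        self,
        model: MotifModel,
        b: np.ndarray,
        weights: np.ndarray,
        rng: np.random.Generator,
        cache: BestSiteCache,
        force_full: bool = False,
        allow_moves: bool = True,
    ):
        """One refinement step.

        Scores the current PWM (via the best-site cache), derives the
        instance membership from the two thresholds, and rebuilds the
        weighted PWM from the members; optionally proposes a column move,
        kept only when it does not decrease the specificity score.  Returns
        (scored_model, next_model, used_cache): ``scored_model`` carries the
        specificity of the incoming PWM, ``next_model`` the rebuilt PWM for
        the next iteration.
        """
        p = self.params
        W = model.pwm.window_width
        s1_mask = b >= model.binding_threshold
        s1 = int(s1_mask.sum())
        T = self.ws.total_positions(W, s1_mask)
        if s1 < 2 or T <= 0:
            return replace(model, dead=True), model, False
        x_prev = model.ctx.x if model.ctx is not None else 1
        prior = motif_prior(s1, x_prev, p.prior_weight_w, T)
        lo, pos, strand, used_cache = self.ws.best_sites(
            model.pwm, cache, p.rescan_kl, p.cache_topk, force_full
        )
        post = posterior_from_log_odds(lo, prior)
        s2_mask = (post >= model.site_threshold) & (pos >= 0)
        member_mask = s1_mask & s2_mask
        x = int(member_mask.sum())
        ctx = SpecificityContext(N=self.ws.N, s1=s1, s2=int(s2_mask.sum()), x=x)
        score = specificity_score(ctx)
        midx = np.flatnonzero(member_mask)
        scored = replace(
            model, ctx=ctx, score=score, member_indices=midx, dead=x < 2
        )
        if x < 2:
            return scored, model, used_cache
        w_m = weights[midx]
        if w_m.sum() <= 0:
            w_m = np.ones_like(w_m)
        sites = [
            Site(int(i), int(pos[i]), "-" if strand[i] else "+", float(lo[i]),
                 float(post[i]))
            for i in midx
        ]
        bases = self.ws.extract_windows(midx, pos[midx], strand[midx], W)
        inst = InstanceSet(sites=sites, base_matrix=bases, weights=w_m)
        new_pwm = build_weighted_pwm(
            inst, W, model.pwm.active, p.pseudocount, self.bg.marginals
        )
        scored.instances = inst
        if allow_moves and p.move_prob > 0 and rng.random() < p.move_prob:
            ctx_bases = self.ws.extract_windows(
                midx, pos[midx], strand[midx], W, pad=p.max_extend
            )
            move_ctx = ColumnContext(
                base_matrix=ctx_bases, pad=p.max_extend, weights=w_m,
                marginals=np.asarray(self.bg.marginals),
            )
            cand = sample_column_move(
                new_pwm, move_ctx, rng,
                min_cols=p.min_cols, max_cols=p.max_cols,
                max_window=p.max_window, max_extend=p.max_extend,
                p_add=p.p_add,
            )
            if cand is not new_pwm:
                # both proposals scored over the same candidate-site pool
                sc_cand, _ = self._score_pwm(
                    cand, b, model.binding_threshold, model.site_threshold, x,
                    cache,
                )
                sc_new, _ = self._score_pwm(
                    new_pwm, b, model.binding_threshold, model.site_threshold,
                    x, cache,
                )
                if sc_cand >= sc_new:
                    new_pwm = cand
                    cache.invalidate()
        nxt = replace(scored, pwm=new_pwm, dead=False)
        return scored, nxt, used_cache

    # -- dynamic threshold phase ------------------------------------------

    def optimize_thresholds(self, pwm: GappedPWM, b: np.ndarray,
                            model: MotifModel):
        """Alternating-threshold phase: jointly maximize the specificity over
        the candidate grid of observed binding scores and posteriors, given
        the current PWM."""
        p = self.params
        s1_mask = b >= model.binding_threshold
        T = self.ws.total_positions(pwm.window_width, s1_mask)
        if T <= 0:
            T = self.ws.total_positions(pwm.window_width)
        x_prev = model.ctx.x if model.ctx is not None else 1
        prior = motif_prior(
            max(int(s1_mask.sum()), 1), x_prev, p.prior_weight_w, T
        )
        lo, _, _, _, _ = self.ws.full_scan(pwm, 1)
        post = posterior_from_log_odds(lo, prior)
        bt, st, ctx, score = optimize_threshold_grid(b, post, p.grid_max)
        member_idx = np.flatnonzero((b >= bt) & (post >= st))
        return bt, st, ctx, score, member_idx

    # -- a full restart ----------------------------------------------------

    def run_restart(self, rng: np.random.Generator,
                    archive_snapshot: list[MotifModel]) -> _RestartResult:
        p = self.params
        dyn_state = None
        if self.dynamics is not None:
            dyn_state = self.dynamics.init_restart(rng)
            b, weights = dyn_state.scores()
            seed_seq = dyn_state.seed_seq
        else:
            b, weights = self.static_b, self.static_w
            seed_seq = None
        try:
            model = self.seed_model(rng, b, seed_seq)
        except ValueError:
            return _RestartResult(None, 0, "seed-failed")
        cache = BestSiteCache()
        best: MotifModel | None = None
        iters = 0
        prev_ctx = None
        thresh_no_improvement = False
        for phase in range(p.max_phases):
            noimp = 0
            phase_iters = 0
            improved_in_phase = False
            while noimp < p.minpass and phase_iters < p.max_iters_per_phase:
                scored, nxt, _ = self.refine_iteration(
                    model, b, weights, rng, cache
                )
                iters += 1
                phase_iters += 1
                at_fixed_point = (
                    prev_ctx is not None
                    and scored.ctx == prev_ctx
                    and nxt.pwm.symmetric_kl(model.pwm) < 1e-12
                )
                prev_ctx = scored.ctx
                if scored.dead:
                    return _RestartResult(best, iters, "dead")
                if best is None or scored.score > best.score + _TOL:
                    best = copy.copy(scored)
                    noimp = 0
                    improved_in_phase = True
                else:
                    noimp += 1
                model = nxt
                if self.dynamics is not None and scored.member_indices is not None:
                    dyn_state.update(scored.member_indices,
                                     weights[scored.member_indices])
                    b, weights = dyn_state.scores()
                if at_fixed_point:
                    break  # deterministic fixed point: go to threshold phase
                if iters % p.check_interval == 0 and archive_snapshot:
                    for m in archive_snapshot:
                        if m.score > (best.score if best else -math.inf) and (
                            compareace_similarity(m.pwm, model.pwm)
                            > p.redundancy_threshold
                        ):
                            return _RestartResult(best, iters, "redundant")
                if (
                    p.early_abandon_iter is not None
                    and iters >= p.early_abandon_iter
                    and (best is None or best.score < p.early_abandon_score)
                ):
                    return _RestartResult(best, iters, "abandoned")
            # termination: a threshold step that brought no improvement,
            # followed by a refinement phase that brought none either
            if thresh_no_improvement and not improved_in_phase:
                return _RestartResult(best, iters, "converged")
            # threshold step: exact re-optimization given the current PWM;
            # the optimized thresholds are always adopted and refinement
            # resumes under them (that re-scoring is what tightens a
            # half-converged model onto its enriched instance set)
            bt, st, ctx, score, member_idx = self.optimize_thresholds(
                model.pwm, b, model
            )
            model = replace(
                model, binding_threshold=bt, site_threshold=st,
                ctx=ctx, score=score, member_indices=member_idx,
            )
            if best is None or score > best.score + _TOL:
                best = copy.copy(model)
                thresh_no_improvement = False
            else:
                thresh_no_improvement = True
            cache.invalidate()  # thresholds changed: force a full rescan
        return _RestartResult(best, iters, "max-phases")

    # -- archive polish ----------------------------------------------------

    def polish_model(self, model: MotifModel,
                     rng: np.random.Generator) -> MotifModel:
        """Re-converge an archived model from its own strongest instance.

        A model can converge to a blurred mixture: its instance set is
        enriched for the true sites but the PWM averages in enough noise
        sites that refinement cannot sharpen it.  Reseeding a one-hot PWM
        from the model's highest-scoring member site (holding the model's
        binding scores fixed) restarts refinement inside the right basin and
        usually locks onto the sharp motif.  The polished model replaces the
        original only when its specificity score is higher.
        """
        p = self.params
        idx = model.member_indices
        if idx is None or len(idx) < 2 or model.ctx is None:
            return model
        scores_for = getattr(self.dynamics, "scores_for", None)
        if scores_for is not None:
            b, weights = scores_for(np.asarray(idx))
        else:
            b, weights = self.static_b, self.static_w
        lo, pos, strand, _, _ = self.ws.full_scan(model.pwm, 1)
        idx = np.asarray(idx)
        order = idx[np.argsort(-lo[idx])]
        W = model.pwm.window_width
        seed_i = None
        for cand in order[:3]:
            cand = int(cand)
            if pos[cand] < 0:
                continue
            win = self.ws.extract_windows(
                np.array([cand]), np.array([pos[cand]]),
                np.array([strand[cand]]), W,
            )[0]
            if (win < 4).all():
                seed_i = cand
                seed_win = win
                break
        if seed_i is None:
            return model
        inst = InstanceSet(
            sites=[Site(seed_i, int(pos[seed_i]),
                        "-" if strand[seed_i] else "+", float(lo[seed_i]))],
            base_matrix=seed_win[None, :],
            weights=np.array([1.0]),
        )
        pwm1 = build_weighted_pwm(inst, W, np.arange(W), p.pseudocount,
                                  self.bg.marginals)
        m = replace(model, pwm=pwm1, ctx=None, score=-math.inf,
                    instances=inst, site_threshold=p.site_threshold_init)
        cache = BestSiteCache()
        best: MotifModel | None = None
        thresh_noimp = False
        dead = False
        for _phase in range(p.max_phases):
            noimp = 0
            improved = False
            prev_ctx = None
            for _ in range(p.max_iters_per_phase):
                scored, nxt, _ = self.refine_iteration(m, b, weights, rng, cache)
                if scored.dead:
                    dead = True
                    break
                at_fixed_point = (
                    prev_ctx is not None and scored.ctx == prev_ctx
                    and nxt.pwm.symmetric_kl(m.pwm) < 1e-12
                )
                prev_ctx = scored.ctx
                if best is None or scored.score > best.score + _TOL:
                    best = copy.copy(scored)
                    noimp = 0
                    improved = True
                else:
                    noimp += 1
                m = nxt
                if noimp >= p.polish_minpass or at_fixed_point:
                    break
            if dead or (thresh_noimp and not improved):
                break
            bt, st, ctx, score, member_idx = self.optimize_thresholds(m.pwm, b, m)
            m = replace(m, binding_threshold=bt, site_threshold=st,
                        ctx=ctx, score=score, member_indices=member_idx)
            if best is None or score > best.score + _TOL:
                best = copy.copy(m)
                thresh_noimp = False
            else:
                thresh_noimp = True
            cache.invalidate()
        if best is not None and best.ctx is not None and best.score > model.score:
            return best
        return model

    # -- the outer loop ----------------------------------------------------

    def run(self) -> MotifArchive:
        p = self.params
        if self.dynamics is not None:
            s1_bp = int(self.ws.lengths.sum())
        else:
            fin = self.static_b[np.isfinite(self.static_b)]
            bt0 = float(np.median(fin)) if fin.size else 0.0
            s1_bp = int(self.ws.lengths[self.static_b >= bt0].sum())
        n_restarts = num_restarts(max(s1_bp, 1), p.window_init, p.sampling_k)
        if p.max_restarts is not None:
            n_restarts = min(n_restarts, p.max_restarts)
        seeds = np.random.SeedSequence(p.seed).spawn(n_restarts)
        archive = MotifArchive(p.redundancy_threshold, p.max_archive)
        done = 0
        while done < n_restarts:
            wave = range(done, min(done + p.wave_size, n_restarts))
            snapshot = archive.snapshot()

            def job(i):
                return self.run_restart(np.random.default_rng(seeds[i]), snapshot)

            if p.workers > 1:
                with ThreadPoolExecutor(max_workers=p.workers) as ex:
                    results = list(ex.map(job, wave))
            else:
                results = [job(i) for i in wave]
            for i, res in zip(wave, results):
                logger.debug(
                    "restart=%d iters=%d reason=%s score=%.3f",
                    i, res.iterations, res.reason,
                    res.model.score if res.model else float("nan"),
                )
                if res.model is not None and res.model.ctx is not None:
                    archive.add(res.model)
            done += len(list(wave))
        if p.polish and len(archive):
            polished = MotifArchive(p.redundancy_threshold, p.max_archive)
            seeds2 = np.random.SeedSequence((p.seed, 1)).spawn(len(archive.models))
            for i, m in enumerate(archive.models[: p.polish_max]):
                polished.add(self.polish_model(m, np.random.default_rng(seeds2[i])))
            for m in archive.models[p.polish_max:]:
                polished.add(m)
            archive = polished
        return archive


def run_search(dataset: Dataset, bg: MarkovBackground,
               params: SearchParams, dynamics=None) -> MotifArchive:
    """Run the full restart loop and return the non-redundant archive."""
    return SearchEngine(dataset, bg, params, dynamics).run()
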