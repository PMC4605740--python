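"""Dynamic expression clustering: motif search where the binding score is
the similarity of a gene's expression to an evolving mean profile.

Instead of clustering genes first and motif-finding second, the expression
profile and the motif are refined jointly: each restart seeds the profile
from one random gene's expression vector and the motif from one random site
of that gene's upstream region; every refinement iteration recomputes each
gene's binding score as its correlation with the current profile, and the
profile is re-estimated as the weighted mean expression of the current
instance set.  The search-space threshold of the core engine is thereby a
correlation threshold, optimized dynamically like any other binding score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pwm import compareace_similarity
from .search import MotifArchive, SearchEngine, SearchParams
from .seqio import Dataset, MarkovBackground

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ExpressionState",
    "ExpressionDynamics",
    "expression_binding_scores",
    "update_profile",
    "run_expression_search",
    "dedupe_by_target_overlap",
]


class ExpressionMatrix:
    """Gene-by-condition expression values with missing entries allowed.

    Genes with fewer than 50 % non-missing entries are dropped with a
    warning; at least two conditions are required.
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        frac = values.notna().mean(axis=1)
        bad = frac < 0.5
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} genes with >50% missing expression",
                stacklevel=2,
            )
            values = values.loc[~bad]
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        self.frame = values

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Header row of condition labels, first column gene id."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=np.float64)


@dataclass
class ExpressionState:
    """The evolving cluster model: a mean expression profile and the
    correlation threshold acting as this mode's binding threshold."""

    profile: np.ndarray
    correlation_threshold: float = 0.0


def expression_binding_scores(
    values: np.ndarray, profile: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene correlation with the profile, missing-aware.

    Returns ``(r, w)`` where r is the centered Pearson coefficient over
    conditions where the gene is observed, and w = (r + 1) / 2 maps it onto
    [0, 1] for use both as the dynamic binding score and as PWM weights.
    Genes with a constant (or near-empty) expression vector get r = 0.
    """
    V = np.asarray(values, dtype=np.float64)
    p = np.asarray(profile, dtype=np.float64)
    if not np.isfinite(p).all():
        p = np.nan_to_num(p)
    if np.ptp(p) == 0:
        raise ValueError("profile is constant; correlations undefined")
    M = np.isfinite(V)
    n = M.sum(axis=1)
    Vf = np.where(M, V, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = Vf.sum(axis=1)
        sxx = (Vf * Vf).sum(axis=1)
        sp = (M * p).sum(axis=1)
        spp = (M * p * p).sum(axis=1)
        sxp = (Vf * p).sum(axis=1)
        cov = sxp - sx * sp / n
        vx = sxx - sx * sx / n
        vp = spp - sp * sp / n
        r = cov / np.sqrt(vx * vp)
    r[~np.isfinite(r)] = 0.0
    r[n < 2] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return r, (r + 1.0) / 2.0


def update_profile(
    values: np.ndarray, members: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted, missing-aware mean expression of the member genes."""
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("cannot update profile from an empty member set")
    V = np.asarray(values, dtype=np.float64)[members]
    w = np.asarray(weights, dtype=np.float64)
    if w.sum() <= 0:
        w = np.ones_like(w)
    M = np.isfinite(V)
    Vf = np.where(M, V, 0.0)
    num = (Vf * w[:, None]).sum(axis=0)
    den = (M * w[:, None]).sum(axis=0)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return out


class _DynState:
    """Per-restart dynamics: the profile this restart is refining."""

    def __init__(self, dynamics: "ExpressionDynamics", seed_gene: int):
        self.dyn = dynamics
        self.seed_seq = seed_gene
        row = dynamics.values[seed_gene]
        self.state = ExpressionState(profile=np.nan_to_num(row))
        self._recompute()

    def _recompute(self) -> None:
        r, w = expression_binding_scores(self.dyn.values, self.state.profile)
        self._b = w
        self._w = w

    def scores(self) -> tuple[np.ndarray, np.ndarray]:
        return self._b, self._w

    def update(self, member_idx: np.ndarray, member_weights: np.ndarray) -> None:
        if self.dyn.freeze or member_idx.size < 2:
            return
        self.state.profile = update_profile(
            self.dyn.values, member_idx, member_weights
        )
        if np.ptp(self.state.profile) == 0:
            return  # degenerate profile: keep previous correlations
        self._recompute()


class ExpressionDynamics:
    """Adapter plugging the evolving expression profile into the search
    engine as its binding-score axis."""

    def __init__(self, values: np.ndarray, freeze: bool = False):
        self.values = np.asarray(values, dtype=np.float64)
        self.freeze = freeze

    def init_restart(self, rng: np.random.Generator) -> _DynState:
        for _ in range(100):
            g = int(rng.integers(self.values.shape[0]))
            row = np.nan_to_num(self.values[g])
            if np.ptp(row) > 0:
                return _DynState(self, g)
        raise ValueError("could not find a non-constant seed expression vector")

    def scores_for(self, member_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Binding scores implied by a fixed member set (used when polishing
        an archived model): correlations with the members' mean profile."""
        profile = update_profile(self.values, member_idx, np.ones(len(member_idx)))
        _, w = expression_binding_scores(self.values, profile)
        return w, w


def run_expression_search(
    upstream_seqs: Dataset,
    expr: ExpressionMatrix,
    bg: MarkovBackground,
    params: SearchParams,
) -> MotifArchive:
    """Joint motif + expression-profile search over all usable genes.

    The universe is every gene present in both the sequence set and the
    expression matrix (N = all usable genes); genes below the correlation
    threshold form the negative set.
    """
    seq_ids = set(upstream_seqs.ids)
    genes = [g for g in expr.genes if g in seq_ids]
    logger.info("expression search: %d usable genes", len(genes))
    if len(genes) < 10:
        raise ValueError(f"only {len(genes)} usable genes (<10)")
    if len(genes) < 100:
        warnings.warn(f"only {len(genes)} usable genes", stacklevel=2)
    sub = Dataset([upstream_seqs[g] for g in genes])
    values = expr.frame.loc[genes].to_numpy(dtype=np.float64)
    dynamics = ExpressionDynamics(values)
    engine = SearchEngine(sub, bg, params, dynamics)
    return engine.run()


def dedupe_by_target_overlap(
    archive: MotifArchive,
    overlap_frac: float = 0.30,
    similarity_gate: float = 0.5,
) -> MotifArchive:
    """Remove motifs whose target-gene sets largely duplicate a better motif.

    Greedy by descending score: a motif is dropped when its target set (the
    x-set of sequences in s1 and s2) overlaps an already-kept motif's targets
    by ``overlap_frac`` or more (|A&B| / min(|A|,|B|); the threshold itself
    is inclusive) *and* the two PWMs are similar (CompareACE above
    ``similarity_gate``), so dissimilar motifs sharing targets survive.
    """
    out = MotifArchive(archive.redundancy_threshold, archive.max_size)
    kept: list = []
    for m in archive.models:
        t = set() if m.member_indices is None else set(map(int, m.member_indices))
        drop = False
        for k in kept:
            kt = set() if k.member_indices is None else set(map(int, k.member_indices))
            if not t or not kt:
                continue
            ov = len(t & kt) / min(len(t), len(kt))
            if ov >= overlap_frac and (
                compareace_similarity(m.pwm, k.pwm) > similarity_gate
            ):
                drop = True
                break
        if not drop:
            kept.append(m)
    out.models = kept
    return out
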