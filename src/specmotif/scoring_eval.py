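"""Motif evaluation: best-site sequence ranking, ROC/auROC, cross-validation,
PBM intensity normalization, randomized-control FDR, and target-overlap tests.

Evaluation ranks sequences by their single highest-scoring site under a PWM
(log-odds, so rankings are prior-free); the area under the ROC curve of that
ranking measures how well the motif separates positives from negatives, with
the Mann-Whitney convention for ties.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .pwm import GappedPWM
from .search import MotifArchive, ScanWorkspace, SearchParams, run_search
from .seqio import Dataset, MarkovBackground
from .specificity import SpecificityContext, specificity_score

logger = logging.getLogger(__name__)

__all__ = [
    "rank_sequences",
    "auroc",
    "roc_points",
    "cross_validate",
    "pbm_normalize",
    "empirical_fdr",
    "FdrResult",
    "target_overlap_pvalue",
]


def rank_sequences(
    pwm: GappedPWM, bg: MarkovBackground, seqs: Dataset
) -> pd.DataFrame:
    """Rank sequences by best-site log-odds over both strands.

    Returns a DataFrame (id, label, score) sorted descending by score with a
    stable sort, so equal-scoring sequences keep input order.  Sequences with
    no valid window score -inf.
    """
    ws = ScanWorkspace(seqs, bg)
    lo, pos, strand, _, _ = ws.full_scan(pwm, 1)
    lo = np.where(pos >= 0, lo, -np.inf)
    df = pd.DataFrame(
        {
            "id": seqs.ids,
            "label": [bool(s.is_positive_label) for s in seqs],
            "score": lo,
        }
    )
    return df.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _finite_scores(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=np.float64)
    if np.isneginf(s).any():
        fin = s[np.isfinite(s)]
        floor = (fin.min() - 1.0) if fin.size else -1.0
        s = np.where(np.isneginf(s), floor, s)
    return s


def auroc(ranked: pd.DataFrame) -> float:
    """Area under the ROC curve of the ranked list.

    Equals the fraction of (positive, negative) pairs correctly ordered with
    ties counted 1/2 (the Mann-Whitney identity).
    """
    y = ranked["label"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("auROC needs at least one positive and one negative")
    return float(roc_auc_score(y, _finite_scores(ranked["score"].to_numpy())))


def roc_points(ranked: pd.DataFrame) -> pd.DataFrame:
    """FPR/TPR points of the ROC curve (monotone by construction)."""
    y = ranked["label"].to_numpy(dtype=bool)
    fpr, tpr, _ = roc_curve(y, _finite_scores(ranked["score"].to_numpy()))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def cross_validate(
    dataset: Dataset,
    bg: MarkovBackground,
    params: SearchParams,
    folds: int = 5,
):
    """Stratified k-fold cross-validation of the search.

    For each fold the search runs on the training split and the top motif is
    scored by auROC on the held-out split.  Returns a list of
    (top_model, test_auroc) per fold plus the mean auROC.
    """
    labels = np.array([bool(s.is_positive_label) for s in dataset])
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds == len(dataset):
        warnings.warn("leave-one-out cross-validation requested", stacklevel=2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=params.seed)
    results = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        if labels[test_idx].all() or not labels[test_idx].any():
            raise ValueError("a fold contains a single class")
        train = Dataset([dataset[int(i)] for i in train_idx])
        test = Dataset([dataset[int(i)] for i in test_idx])
        archive = run_search(train, bg, params)
        if archive.best is None:
            results.append((None, float("nan")))
            continue
        ranked = rank_sequences(archive.best.pwm, bg, test)
        results.append((archive.best, auroc(ranked)))
    mean_auc = float(np.nanmean([a for _, a in results]))
    return results, mean_auc


def pbm_normalize(raw_scores: np.ndarray) -> np.ndarray:
    """Normalize probe intensities to (0, 1) binding scores via a log-normal
    null.

    Raw scores are translated to strictly positive values (min-shift + 1), a
    log-normal is fitted by maximum likelihood, and each probe's binding
    score is the fitted CDF at its translated intensity — strictly increasing
    in the raw score, with the fitted median mapping to 0.5.  Probes bound by
    the assayed factor sit in the extreme upper tail (scores near 1); the
    conventional cutoffs call probes above 0.9 bound and below 0.5 unbound.
    Non-finite raw scores propagate as NaN (count logged).
    """
    raw = np.asarray(raw_scores, dtype=np.float64)
    fin = np.isfinite(raw)
    n_bad = int((~fin).sum())
    if n_bad:
        logger.warning("pbm_normalize: dropping %d non-finite scores", n_bad)
    v = raw[fin]
    if v.size < 100:
        warnings.warn("fewer than 100 probes; log-normal fit will be crude",
                      stacklevel=2)
    # translate to strictly positive values only when needed (min-shift + 1);
    # already-positive intensities are left untouched
    if v.min() <= 0:
        v = v - v.min() + 1.0
    z = np.log(v)
    mu, sigma = float(z.mean()), float(z.std())
    if sigma == 0:
        raise ValueError("all probe intensities identical")
    out = np.full_like(raw, np.nan)
    eps = 1e-12
    out[fin] = np.clip(stats.norm.cdf((z - mu) / sigma), eps, 1 - eps)
    return out


@dataclass
class FdrResult:
    """Empirical FDR from a randomized-sequence negative control."""

    fdr: float
    n_real: int
    n_randomized: int


def empirical_fdr(
    real_archive: MotifArchive,
    randomized_archive: MotifArchive,
    score_cutoff: float,
) -> FdrResult:
    """FDR at a score cutoff: motifs found in randomized (k-let shuffled)
    input at the cutoff, over motifs found in the real input."""
    n_real = sum(1 for m in real_archive if m.score >= score_cutoff)
    n_rand = sum(1 for m in randomized_archive if m.score >= score_cutoff)
    if n_real == 0:
        return FdrResult(float("nan"), 0, n_rand)
    return FdrResult(n_rand / n_real, n_real, n_rand)


def target_overlap_pvalue(targets_a, targets_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value of the overlap of two target sets
    within a common universe (p = 10 ** -specificity score)."""
    a, b = set(targets_a), set(targets_b)
    if universe_size < max(len(a), len(b)):
        raise ValueError("universe smaller than a target set")
    ctx = SpecificityContext(
        N=universe_size, s1=len(a), s2=len(b), x=len(a & b)
    )
    return float(10.0 ** (-specificity_score(ctx)))
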