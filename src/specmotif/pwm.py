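"""Gapped position weight matrix model: site scoring, Bayesian posterior,
weighted matrix estimation, column moves, and motif similarity.

The motif model spans a window of ``window_width`` positions of which only the
``active_columns`` are informative; internal inactive positions are gaps, as
in dimeric sites like Gal4's CGG-(11 bp)-GGC.  The likelihood ratio of a site
is the product over *active* columns only of f_{j,b} over the background
probability of the same base given its actual sequence context; gap columns
contribute to neither numerator nor denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .seqio import MarkovBackground, revcomp, encode

__all__ = [
    "GappedPWM",
    "Site",
    "InstanceSet",
    "site_likelihood_ratio",
    "site_log_odds",
    "motif_prior",
    "site_posterior",
    "posterior_from_log_odds",
    "build_weighted_pwm",
    "compareace_similarity",
    "sample_column_move",
    "ColumnContext",
    "write_meme",
]

_EPS = 1e-12


@dataclass
class GappedPWM:
    """A PWM over ``window_width`` positions with gaps allowed internally.

    freqs has one probability row per *active* column, in active-column
    order.  The first and last window positions are always active (gaps are
    internal), so the window is anchored by informative columns.
    """

    window_width: int
    active: np.ndarray  # sorted int offsets within the window
    freqs: np.ndarray  # (width_w, 4) row-stochastic
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.active.size < 1 or self.active.size > self.window_width:
            raise ValueError("need 1 <= |active_columns| <= window_width")
        if not np.all(np.diff(self.active) > 0):
            raise ValueError("active columns must be strictly increasing")
        if self.active[0] != 0 or self.active[-1] != self.window_width - 1:
            raise ValueError("first and last window positions must be active")
        if self.freqs.shape != (self.active.size, 4):
            raise ValueError("freqs shape must be (len(active), 4)")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each active column must sum to 1")

    @property
    def width_w(self) -> int:
        """Number of active (informative) columns: the 'w' of the restart
        formula."""
        return int(self.active.size)

    @property
    def log_freqs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.freqs)

    @property
    def consensus(self) -> str:
        """Argmax base per window position, '.' at gaps."""
        out = ["."] * self.window_width
        for row, j in zip(self.freqs, self.active):
            out[int(j)] = "ACGT"[int(np.argmax(row))]
        return "".join(out)

    def window_matrix(self, fill: np.ndarray | None = None) -> np.ndarray:
        """(window_width, 4) matrix with gap columns filled by ``fill``
        (uniform by default)."""
        q = np.full(4, 0.25) if fill is None else np.asarray(fill, dtype=float)
        m = np.tile(q, (self.window_width, 1))
        m[self.active] = self.freqs
        return m

    def reverse_complement(self) -> "GappedPWM":
        new_active = np.sort(self.window_width - 1 - self.active)
        new_freqs = self.freqs[::-1, ::-1].copy()
        return GappedPWM(self.window_width, new_active, new_freqs, self.pseudocount)

    def symmetric_kl(self, other: "GappedPWM") -> float:
        """Symmetrized KL divergence summed over columns; inf when the
        geometries differ (used as the rescan-trigger fingerprint distance)."""
        if (
            self.window_width != other.window_width
            or self.active.size != other.active.size
            or not np.array_equal(self.active, other.active)
        ):
            return math.inf
        p = np.clip(self.freqs, _EPS, 1.0)
        q = np.clip(other.freqs, _EPS, 1.0)
        return float(((p - q) * (np.log(p) - np.log(q))).sum())


@dataclass
class Site:
    """One candidate motif instance: a window on one strand of one sequence.

    ``pos`` is the plus-strand window start (0-based); strand '-' means the
    reverse complement of that interval is the instance read 5'->3'.
    """

    seq_index: int
    pos: int
    strand: str
    log_odds: float
    posterior: float = float("nan")

    @property
    def likelihood_ratio(self) -> float:
        return math.exp(self.log_odds)


@dataclass
class InstanceSet:
    """The current motif instances: at most one best site per sequence, with
    per-site weights w_i in [0, 1] (normalized binding scores)."""

    sites: list[Site]
    base_matrix: np.ndarray  # (n, window_width) int8, site windows oriented 5'->3'
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.min(initial=0.0) < 0 or self.weights.max(initial=0.0) > 1:
            raise ValueError("weights must lie in [0, 1]")
        idx = [s.seq_index for s in self.sites]
        if len(set(idx)) != len(idx):
            raise ValueError("at most one site per sequence")

    @property
    def n(self) -> int:
        return len(self.sites)


def site_log_odds(
    pwm: GappedPWM, bg: MarkovBackground, seq: str, pos: int, strand: str = "+"
) -> float:
    """log L for the window at [pos, pos+window_width) on ``strand``.

    Reference implementation (the search engine uses a compiled equivalent).
    Returns -inf when a zero-frequency column meets a mismatching base.
    """
    W = pwm.window_width
    if pos < 0 or pos + W > len(seq):
        raise ValueError(f"window [{pos}, {pos + W}) out of range")
    window = seq[pos : pos + W]
    if "N" in window:
        raise ValueError("window contains N")
    if strand == "-":
        window = revcomp(window)
    logf = pwm.log_freqs
    total = 0.0
    for row, j in zip(logf, pwm.active):
        j = int(j)
        b = window[j]
        lf = row["ACGT".index(b)]
        if lf == -math.inf:
            return -math.inf
        # background term: base j of the standalone window, conditioned on
        # its min(order, j) preceding window bases
        total += lf - bg.column_log_prob(window, j)
    return total


def site_likelihood_ratio(
    pwm: GappedPWM, bg: MarkovBackground, seq: str, pos: int, strand: str = "+"
) -> float:
    """L = Pr(S | theta) / Pr(S | theta_0), over active columns only."""
    lo = site_log_odds(pwm, bg, seq, pos, strand)
    return math.exp(lo)


def motif_prior(s1: int, x: int, prior_weight_w: float, T: int) -> float:
    """Prior probability that a random search-space position is a motif site.

    Pr(theta) = (s1*w + x*(1-w)) / T, assuming one instance per search-space
    sequence in place of a hand-tuned expected-count parameter; clamped to
    (eps, 1-eps).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not (0.0 <= prior_weight_w <= 1.0):
        raise ValueError("prior weight must be in [0, 1]")
    p = (s1 * prior_weight_w + x * (1.0 - prior_weight_w)) / T
    return float(min(max(p, _EPS), 1.0 - _EPS))


def site_posterior(L: float, prior: float) -> float:
    """Pr(theta | S) = L p / (L p + 1 - p); monotone in both arguments."""
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must be in (0, 1)")
    if L < 0:
        raise ValueError("likelihood ratio must be >= 0")
    if math.isinf(L):
        return 1.0
    num = L * prior
    return num / (num + 1.0 - prior)


def posterior_from_log_odds(log_odds, prior: float):
    """Vector-friendly posterior: sigmoid(log L + logit(prior))."""
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must be in (0, 1)")
    return expit(np.asarray(log_odds, dtype=np.float64) + math.log(prior / (1.0 - prior)))


def build_weighted_pwm(
    instances: InstanceSet,
    window_width: int,
    active_columns: np.ndarray,
    pseudocount: float = 0.5,
    background_marginals: np.ndarray | None = None,
) -> GappedPWM:
    """Estimate the weighted PWM from the current instances.

    f_{j,b} = (sum_i I_{i,j,b} w_i + pc * q_b) / (sum_i w_i + pc), where w is
    the vector of normalized binding scores, so high-scoring sequences shape
    the matrix more than marginal ones.  With equal weights this reduces
    exactly to the unweighted count matrix.
    """
    if instances.n < 1:
        raise ValueError("need at least one instance")
    wsum = float(instances.weights.sum())
    if wsum <= 0:
        raise ValueError("all instance weights are zero (degenerate search space)")
    q = (
        np.full(4, 0.25)
        if background_marginals is None
        else np.asarray(background_marginals, dtype=float)
    )
    active_columns = np.asarray(active_columns, dtype=np.int64)
    k = active_columns.size
    counts = np.zeros((k, 4))
    B = instances.base_matrix[:, active_columns]
    for b in range(4):
        counts[:, b] = ((B == b) * instances.weights[:, None]).sum(axis=0)
    freqs = (counts + pseudocount * q) / (wsum + pseudocount)
    freqs /= freqs.sum(axis=1, keepdims=True)
    return GappedPWM(window_width, active_columns, freqs, pseudocount)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    d = math.sqrt((xc @ xc) * (yc @ yc))
    if d == 0:
        return 0.0
    return float((xc @ yc) / d)


def compareace_similarity(
    a: GappedPWM, b: GappedPWM, min_overlap: int = 6
) -> float:
    """Best-alignment correlation between two PWMs' frequency matrices.

    Maximum over all ungapped offsets and both orientations of ``b`` of the
    Pearson correlation between aligned frequency entries (4 values per
    aligned column pair); gap columns enter as the uniform distribution so
    dimer spacing is respected.  Symmetric in its arguments.  Overlaps
    shorter than min(min_overlap, min window width) are not considered.
    """
    wa, wb = a.window_width, b.window_width
    ov_min = min(min_overlap, wa, wb)
    ma = a.window_matrix()
    best = -1.0
    found = False
    for mb in (b.window_matrix(), b.reverse_complement().window_matrix()):
        for off in range(-(wb - ov_min), wa - ov_min + 1):
            lo_a, hi_a = max(0, off), min(wa, off + wb)
            if hi_a - lo_a < ov_min:
                continue
            found = True
            xa = ma[lo_a:hi_a].ravel()
            xb = mb[lo_a - off : hi_a - off].ravel()
            best = max(best, _pearson(xa, xb))
    if not found:
        warnings.warn("no admissible overlap between PWMs", stacklevel=2)
        return -1.0
    return best


@dataclass
class ColumnContext:
    """Aligned sequence context around the current instances, used to
    estimate frequencies for newly added columns.

    base_matrix holds, per instance, the bases of the window plus ``pad``
    flanking positions on each side (encoded 0-3; 4 marks N or positions
    beyond the sequence end).
    """

    base_matrix: np.ndarray  # (n, pad + window + pad) int8
    pad: int
    weights: np.ndarray
    marginals: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))


def _column_freqs(
    col: np.ndarray, weights: np.ndarray, pseudocount: float, q: np.ndarray
) -> np.ndarray:
    valid = col < 4
    if not valid.any():
        return q.copy()
    w = weights[valid]
    counts = np.zeros(4)
    for b in range(4):
        counts[b] = w[col[valid] == b].sum()
    f = (counts + pseudocount * q) / (w.sum() + pseudocount)
    return f / f.sum()


def sample_column_move(
    pwm: GappedPWM,
    context: ColumnContext,
    rng: np.random.Generator,
    min_cols: int = 6,
    max_cols: int = 24,
    max_window: int = 30,
    max_extend: int = 3,
    p_add: float = 0.5,
) -> GappedPWM:
    """Propose a PWM with one column added or removed.

    Additions are sampled from unoccupied window positions or window
    extensions of at most ``max_extend`` on either flank; the new column's
    frequencies are estimated from the aligned instance context.  Removals
    drop one active column; removing a flank column shrinks the window to the
    next active column so the window stays anchored.  Returns the input
    unchanged when no legal move exists.
    """
    k = pwm.width_w
    W = pwm.window_width
    pad = context.pad

    add_slots: list[int] = []
    if k + 1 <= max_cols:
        occupied = set(int(j) for j in pwm.active)
        add_slots.extend(j for j in range(W) if j not in occupied)
        for d in range(1, min(max_extend, pad) + 1):
            if W + d <= max_window:
                add_slots.append(-d)  # extend left
                add_slots.append(W - 1 + d)  # extend right
    can_remove = k - 1 >= min_cols and k > 1

    do_add: bool
    if add_slots and can_remove:
        do_add = rng.random() < p_add
    elif add_slots:
        do_add = True
    elif can_remove:
        do_add = False
    else:
        return pwm

    if do_add:
        t = int(add_slots[rng.integers(len(add_slots))])
        col = context.base_matrix[:, pad + t]
        newf = _column_freqs(col, context.weights, pwm.pseudocount, context.marginals)
        if t < 0:  # left extension: window start moves left by -t
            shift = -t
            active = np.concatenate([[0], pwm.active + shift])
            freqs = np.vstack([newf, pwm.freqs])
            return GappedPWM(W + shift, active, freqs, pwm.pseudocount)
        if t >= W:  # right extension
            active = np.concatenate([pwm.active, [t]])
            freqs = np.vstack([pwm.freqs, newf])
            return GappedPWM(t + 1, active, freqs, pwm.pseudocount)
        pos = int(np.searchsorted(pwm.active, t))
        active = np.insert(pwm.active, pos, t)
        freqs = np.insert(pwm.freqs, pos, newf, axis=0)
        return GappedPWM(W, active, freqs, pwm.pseudocount)

    # removal
    ridx = int(rng.integers(k))
    active = np.delete(pwm.active, ridx)
    freqs = np.delete(pwm.freqs, ridx, axis=0)
    start, end = int(active[0]), int(active[-1])
    return GappedPWM(end - start + 1, active - start, freqs, pwm.pseudocount)


def read_meme(path) -> tuple[list[GappedPWM], list[str]]:
    """Read motifs from MEME minimal format (all window columns active)."""
    pwms, names = [], []
    rows: list[list[float]] = []
    name = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                if name is not None and rows:
                    m = np.array(rows)
                    pwms.append(GappedPWM(len(rows), np.arange(len(rows)),
                                          m / m.sum(axis=1, keepdims=True)))
                    names.append(name)
                name = s.split()[1]
                rows = []
            elif name is not None and s and not s.startswith("letter-probability"):
                parts = s.split()
                if len(parts) == 4:
                    try:
                        rows.append([float(v) for v in parts])
                    except ValueError:
                        pass
    if name is not None and rows:
        m = np.array(rows)
        pwms.append(GappedPWM(len(rows), np.arange(len(rows)),
                              m / m.sum(axis=1, keepdims=True)))
        names.append(name)
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms, names


def write_meme(
    pwms: list[GappedPWM],
    path,
    names: list[str] | None = None,
    background: np.ndarray | None = None,
    nsites: list[int] | None = None,
) -> None:
    """Write motifs in MEME minimal format.

    Gapped PWMs are written over their full window with gap columns set to
    the background marginals, preserving dimer spacing.
    """
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {q[0]:.5f} C {q[1]:.5f} G {q[2]:.5f} T {q[3]:.5f}\n\n"
        )
        for i, p in enumerate(pwms):
            name = names[i] if names else f"motif_{i + 1}"
            m = p.window_matrix(fill=q)
            n = nsites[i] if nsites else 20
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.window_width} "
                f"nsites= {n} E= 0\n"
            )
            for row in m:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
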