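"""Hypergeometric group-specificity objective.

The discriminative objective optimized by the search engine is the *specificity
score*: the negative log (base 10) of the upper-tail probability that ``x`` or
more of the ``s2`` motif-containing sequences fall inside the ``s1`` positive
search space, out of ``N`` total sequences, under the hypergeometric null

    P(X >= x),  X ~ Hypergeometric(N, s1, s2).

A high score means the motif's instance set is concentrated in the positive
search space far beyond chance, i.e. the motif is *specific* rather than merely
over-represented.  Because genomic ``N`` is large, the tail sum is accumulated
entirely in log space using the classic log-sum trick; terms are added starting
from the largest (the in-tail mode) so the pivot of every ``log_add`` is the
running maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln

__all__ = [
    "SpecificityContext",
    "log_add",
    "log_hypergeom_pmf",
    "specificity_score",
]

_LN10 = math.log(10.0)
# relative size at which additional tail terms stop contributing at double precision
_TERM_EPS_LOG = math.log(1e-18)


@dataclass(frozen=True)
class SpecificityContext:
    """Counts feeding the hypergeometric objective.

    N : total sequences (positive + negative universe)
    s1 : sequences at or above the binding-score threshold (the search space)
    s2 : sequences whose best site passes the sequence-score threshold,
         counted over all N sequences
    x : size of the intersection of the two sets
    """

    N: int
    s1: int
    s2: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.s1 <= self.N and 0 <= self.s2 <= self.N):
            raise ValueError(
                f"invalid counts: N={self.N}, s1={self.s1}, s2={self.s2}"
            )
        if not (0 <= self.x <= min(self.s1, self.s2)):
            raise ValueError(
                f"x={self.x} outside [0, min(s1,s2)={min(self.s1, self.s2)}]"
            )


def log_add(log_x: float, log_y: float) -> float:
    """Return ``log(x + y)`` given ``log(x)`` and ``log(y)``.

    Stable for arbitrarily small operands: the larger argument is used as the
    pivot, so ``log(x + y) = log(x) + log(1 + exp(log(y) - log(x)))`` never
    underflows the result.  ``-inf`` operands (zero terms) are identities.
    """
    if log_x == -math.inf:
        return log_y
    if log_y == -math.inf:
        return log_x
    if log_y > log_x:
        log_x, log_y = log_y, log_x
    return log_x + math.log1p(math.exp(log_y - log_x))


def log_hypergeom_pmf(ctx: SpecificityContext, i: int) -> float:
    """Natural log of ``C(s1,i) C(N-s1, s2-i) / C(N, s2)`` via log-gamma.

    Returns ``-inf`` for ``i`` outside the support
    ``[max(0, s1+s2-N), min(s1, s2)]``.
    """
    N, s1, s2 = ctx.N, ctx.s1, ctx.s2
    if i < max(0, s1 + s2 - N) or i > min(s1, s2):
        return -math.inf
    return float(
        gammaln(s1 + 1)
        - gammaln(i + 1)
        - gammaln(s1 - i + 1)
        + gammaln(N - s1 + 1)
        - gammaln(s2 - i + 1)
        - gammaln(N - s1 - s2 + i + 1)
        + gammaln(s2 + 1)
        + gammaln(N - s2 + 1)
        - gammaln(N + 1)
    )


def _log_tail(N: int, s1: int, s2: int, x: int) -> float:
    """log P(X >= x) for X ~ Hypergeometric(N, s1, s2), summed in log space.

    Terms are accumulated from the largest one (the mode of the pmf clamped
    into the tail) downward; the ascending side is truncated once a term falls
    below 1e-16 of the running sum, but the i = x term is always included.
    """
    lo = max(0, s1 + s2 - N)
    hi = min(s1, s2)
    if x <= lo:
        return 0.0
    ctx = SpecificityContext(N, s1, s2, x)
    # mode of the hypergeometric pmf
    mode = int(math.floor((s1 + 1) * (s2 + 1) / (N + 2)))
    if x <= mode and (x - lo) < (hi - x):
        # below the mode the complementary (lower) sum has fewer terms and,
        # because it is small, its absolute error shrinks with it — more
        # accurate than accumulating the near-unit tail directly
        csum = log_hypergeom_pmf(ctx, x - 1)
        for i in range(x - 2, lo - 1, -1):
            t = log_hypergeom_pmf(ctx, i)
            if t - csum < _TERM_EPS_LOG:
                break
            csum = log_add(csum, t)
        if csum >= 0.0:
            return -math.inf
        return math.log1p(-math.exp(csum))
    m0 = min(max(x, mode), hi)
    total = log_hypergeom_pmf(ctx, m0)
    # descend toward x; truncate once terms are negligible relative to the
    # running sum, but always include the i = x term itself
    stopped = False
    for i in range(m0 - 1, x - 1, -1):
        t = log_hypergeom_pmf(ctx, i)
        if t - total < _TERM_EPS_LOG:
            stopped = True
            break
        total = log_add(total, t)
    if stopped:
        total = log_add(total, log_hypergeom_pmf(ctx, x))
    # ascend toward hi with early termination on negligible terms
    for i in range(m0 + 1, hi + 1):
        t = log_hypergeom_pmf(ctx, i)
        if t - total < _TERM_EPS_LOG:
            break
        total = log_add(total, t)
    return min(total, 0.0)


def specificity_score(ctx: SpecificityContext) -> float:
    """Specificity score: ``-log10 P(X >= x)``, ``X ~ Hypergeom(N, s1, s2)``.

    Zero when ``x`` is at or below the support minimum (the tail is then the
    whole distribution).  Monotone non-decreasing in ``x`` at fixed
    ``(N, s1, s2)`` and symmetric under swapping ``s1`` and ``s2``.
    """
    lt = _log_tail(ctx.N, ctx.s1, ctx.s2, ctx.x)
    return max(0.0, -lt / _LN10)
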