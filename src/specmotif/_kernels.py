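"""Numba kernels for sequence scanning and hypergeometric tail scoring.

These mirror the pure-Python reference implementations in ``seqio``, ``pwm``
and ``specificity``; tests assert their agreement.  All kernels are cached to
disk so compilation happens once per installation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LN10 = math.log(10.0)
_TERM_EPS_LOG = math.log(1e-18)


@njit(cache=True)
def position_bg_logprobs(E, lengths, logflat, offs, order):
    """Per-position background log-probabilities at every context length.

    Bp[oo, n, i] = log P(base_i | the min(oo, i) preceding plus-strand
    bases); Bm[oo, n, i] = log P(complement(base_i) | the complemented
    downstream bases), i.e. the minus-strand reading.  Windows are scored
    standalone: a window column at offset a uses truncation level
    min(order, a), so its context never leaves the window.  Contexts
    crossing an N fall back to the longest valid shorter context.
    """
    N, L = E.shape
    Bp = np.zeros((order + 1, N, L))
    Bm = np.zeros((order + 1, N, L))
    for n in range(N):
        M = lengths[n]
        for i in range(M):
            b = E[n, i]
            if b > 3:
                continue
            for o in range(order + 1):
                # plus strand, target context length o
                oo = o if o < i else i
                t = 0
                while t < oo and E[n, i - t - 1] <= 3:
                    t += 1
                oo = t
                code = 0
                for t in range(oo, 0, -1):
                    code = code * 4 + E[n, i - t]
                Bp[o, n, i] = logflat[offs[oo] + code * 4 + b]
                # minus strand, context downstream (complemented)
                rem = M - 1 - i
                oo = o if o < rem else rem
                t = 0
                while t < oo and E[n, i + t + 1] <= 3:
                    t += 1
                oo = t
                code = 0
                for t in range(oo, 0, -1):
                    code = code * 4 + (3 - E[n, i + t])
                Bm[o, n, i] = logflat[offs[oo] + code * 4 + (3 - b)]
    return Bp, Bm


@njit(cache=True, inline="always")
def _topk_insert(cand_lo, cand_pos, cand_str, lo, pos, st):
    K = cand_lo.shape[0]
    if lo <= cand_lo[K - 1]:
        return
    j = K - 1
    while j > 0 and cand_lo[j - 1] < lo:
        cand_lo[j] = cand_lo[j - 1]
        cand_pos[j] = cand_pos[j - 1]
        cand_str[j] = cand_str[j - 1]
        j -= 1
    cand_lo[j] = lo
    cand_pos[j] = pos
    cand_str[j] = st


@njit(cache=True)
def full_scan_topk(E, Bp, Bm, CBp, CBm, lengths, logf, active, lvl, W, K):
    """Scan every valid window on both strands of every sequence.

    Returns the per-sequence top-K candidate list (best site first) that
    seeds the best-site cache.  Windows containing N at an active column
    are skipped; ties keep the earlier site (plus strand first at equal
    start).  ``lvl[t]`` is the background truncation level of active column
    t (min(order, offset)), so each window is scored standalone.

    Lookahead pruning drops a window as soon as its running score plus a
    true upper bound on the remaining columns cannot reach the current
    K-th best; the bound combines the suffix-summed per-column maximum
    motif log-frequency with prefix sums (CBp/CBm) of the largest negated
    background term at each position, so results are never changed.
    """
    N = E.shape[0]
    na = active.shape[0]
    cand_lo = np.full((N, K), -np.inf)
    cand_pos = np.full((N, K), -1, dtype=np.int32)
    cand_str = np.zeros((N, K), dtype=np.int8)
    colmax = np.empty(na)
    for t in range(na):
        m = logf[active[t], 0]
        for b in range(1, 4):
            if logf[active[t], b] > m:
                m = logf[active[t], b]
        colmax[t] = m
    suff = np.zeros(na + 1)
    for t in range(na - 1, -1, -1):
        suff[t] = suff[t + 1] + colmax[t]
    prune_at = na // 3
    for n in range(N):
        M = lengths[n]
        kth = cand_lo[n, K - 1]
        for p in range(M - W + 1):
            acc = 0.0
            ok = True
            for t in range(na):
                a = active[t]
                b = E[n, p + a]
                if b > 3:
                    ok = False
                    break
                acc += logf[a, b] - Bp[lvl[t], n, p + a]
                if t == prune_at:
                    bound = suff[t + 1] + (CBp[n, p + W] - CBp[n, p + a + 1])
                    if acc + bound + 1e-6 < kth:
                        ok = False
                        break
            if ok:
                _topk_insert(cand_lo[n], cand_pos[n], cand_str[n], acc, p, 0)
                kth = cand_lo[n, K - 1]
            acc = 0.0
            ok = True
            for t in range(na):
                a = active[t]
                i = p + W - 1 - a
                b = E[n, i]
                if b > 3:
                    ok = False
                    break
                acc += logf[a, 3 - b] - Bm[lvl[t], n, i]
                if t == prune_at:
                    bound = suff[t + 1] + (CBm[n, p + W - 1 - a] - CBm[n, p])
                    if acc + bound + 1e-6 < kth:
                        ok = False
                        break
            if ok:
                _topk_insert(cand_lo[n], cand_pos[n], cand_str[n], acc, p, 1)
                kth = cand_lo[n, K - 1]
    return cand_lo, cand_pos, cand_str


@njit(cache=True)
def rescan_candidates(E, Bp, Bm, lengths, cand_pos, cand_str, logf, active, lvl, W):
    """Rescore only the cached candidate sites under the current PWM and
    return the best per sequence (the cache fast path).  Accumulation order
    matches full_scan_topk exactly, so a cached site's score is bitwise
    identical to its full-scan score."""
    N = E.shape[0]
    K = cand_pos.shape[1]
    na = active.shape[0]
    best_lo = np.full(N, -np.inf)
    best_pos = np.full(N, -1, dtype=np.int32)
    best_str = np.zeros(N, dtype=np.int8)
    for n in range(N):
        for c in range(K):
            p = cand_pos[n, c]
            if p < 0 or p + W > lengths[n]:
                continue
            acc = 0.0
            ok = True
            if cand_str[n, c] == 0:
                for t in range(na):
                    a = active[t]
                    b = E[n, p + a]
                    if b > 3:
                        ok = False
                        break
                    acc += logf[a, b] - Bp[lvl[t], n, p + a]
            else:
                for t in range(na):
                    a = active[t]
                    i = p + W - 1 - a
                    b = E[n, i]
                    if b > 3:
                        ok = False
                        break
                    acc += logf[a, 3 - b] - Bm[lvl[t], n, i]
            if ok and acc > best_lo[n]:
                best_lo[n] = acc
                best_pos[n] = p
                best_str[n] = cand_str[n, c]
    return best_lo, best_pos, best_str


@njit(cache=True, inline="always")
def _log_pmf(N, s1, s2, i):
    return (
        math.lgamma(s1 + 1)
        - math.lgamma(i + 1)
        - math.lgamma(s1 - i + 1)
        + math.lgamma(N - s1 + 1)
        - math.lgamma(s2 - i + 1)
        - math.lgamma(N - s1 - s2 + i + 1)
        + math.lgamma(s2 + 1)
        + math.lgamma(N - s2 + 1)
        - math.lgamma(N + 1)
    )


@njit(cache=True, inline="always")
def _log_add(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    if b > a:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def spec_scores_vec(N, s1v, s2v, xv):
    """Vectorized specificity score: -log10 P(X >= x), X ~ Hypergeom.

    Same largest-term-first log-space accumulation as the scalar reference;
    the descending side is truncated once terms are negligible, but the i=x
    term is always included.
    """
    n = s1v.shape[0]
    out = np.empty(n)
    for idx in range(n):
        s1 = s1v[idx]
        s2 = s2v[idx]
        x = xv[idx]
        lo = s1 + s2 - N
        if lo < 0:
            lo = 0
        hi = s1 if s1 < s2 else s2
        if x <= lo:
            out[idx] = 0.0
            continue
        mode = int(math.floor((s1 + 1.0) * (s2 + 1.0) / (N + 2.0)))
        if x <= mode and (x - lo) < (hi - x):
            # below the mode the complement (lower) sum has fewer terms and
            # the tail is large, so linear-space subtraction is safe
            m1 = x - 1
            csum = _log_pmf(N, s1, s2, m1)
            for i in range(m1 - 1, lo - 1, -1):
                t = _log_pmf(N, s1, s2, i)
                if t - csum < _TERM_EPS_LOG:
                    break
                csum = _log_add(csum, t)
            tail = 1.0 - math.exp(csum)
            if tail <= 0.0:
                out[idx] = 0.0
            else:
                sc = -math.log10(tail)
                out[idx] = sc if sc > 0.0 else 0.0
            continue
        m0 = x if x > mode else mode
        if m0 > hi:
            m0 = hi
        total = _log_pmf(N, s1, s2, m0)
        stopped = False
        for i in range(m0 - 1, x - 1, -1):
            t = _log_pmf(N, s1, s2, i)
            if t - total < _TERM_EPS_LOG:
                stopped = True
                break
            total = _log_add(total, t)
        if stopped:
            total = _log_add(total, _log_pmf(N, s1, s2, x))
        for i in range(m0 + 1, hi + 1):
            t = _log_pmf(N, s1, s2, i)
            if t - total < _TERM_EPS_LOG:
                break
            total = _log_add(total, t)
        if total > 0.0:
            total = 0.0
        sc = -total / _LN10
        out[idx] = sc if sc > 0.0 else 0.0
    return out
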