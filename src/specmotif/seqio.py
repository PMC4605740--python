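"""Sequence and score-table I/O, Markov backgrounds, matched negative sets.

Coordinates are 0-based half-open throughout.  Strand "-" means the reverse
complement of the plus-strand interval is scored; sites are always reported
with plus-strand coordinates.  Soft-masked (lowercase) input is uppercased on
read and its lowercase fraction retained as the per-sequence repeat fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ScoredSequence",
    "Dataset",
    "MarkovBackground",
    "read_fasta",
    "write_fasta",
    "attach_scores",
    "fit_markov_background",
    "background_log_prob",
    "generate_matched_negatives",
    "klet_shuffle",
    "encode",
    "decode",
    "revcomp",
]

_ALPHABET = "ACGTN"
_ENC = {c: i for i, c in enumerate(_ALPHABET)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return s.translate(_COMP)[::-1]


_ENC_LUT = np.full(256, -1, dtype=np.int8)
for _c, _i in _ENC.items():
    _ENC_LUT[ord(_c)] = _i


def encode(s: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 (int8)."""
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out = _ENC_LUT[raw]
    if (out < 0).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return out


def decode(arr: np.ndarray) -> str:
    return "".join(_ALPHABET[int(i)] for i in arr)


@dataclass
class ScoredSequence:
    """A DNA sequence with an optional continuous binding score.

    The binding score is the dynamic-search-space axis: ChIP read depth, PBM
    probe intensity, or (in expression mode) a similarity to an evolving
    expression profile.  ``is_positive_label`` supports the degenerate
    fixed-search-space mode where positives/negatives are given as labels.
    """

    id: str
    bases: str
    binding_score: float | None = None
    is_positive_label: bool | None = None
    repeat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - set(_ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )
        if self.binding_score is not None and not math.isfinite(self.binding_score):
            raise ValueError(f"sequence {self.id!r} has non-finite binding score")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def gc(self) -> float:
        n = sum(1 for c in self.bases if c in "GC")
        acgt = sum(1 for c in self.bases if c != "N")
        return n / acgt if acgt else 0.0


class Dataset:
    """An ordered collection of ScoredSequence with unique ids.

    ``total_positions`` is T, the number of scannable window start positions
    (both strands) in the current search space; it must be recomputed whenever
    search-space membership or the window width changes.
    """

    def __init__(self, sequences: Iterable[ScoredSequence]):
        self.sequences: list[ScoredSequence] = list(sequences)
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes[:5]}")
        self._index = {s.id: i for i, s in enumerate(self.sequences)}

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.sequences[self._index[key]]
        return self.sequences[key]

    def __iter__(self):
        return iter(self.sequences)

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences], dtype=np.int64)

    def binding_scores(self, default: float = -math.inf) -> np.ndarray:
        """Per-sequence binding score; sequences without one get ``default``
        (-inf: never in the search space under any threshold)."""
        return np.array(
            [s.binding_score if s.binding_score is not None else default
             for s in self.sequences],
            dtype=np.float64,
        )

    def normalized_scores(self) -> np.ndarray:
        """Binding scores min-max normalized to [0, 1] for use as PWM weights.

        Sequences without a score get 0 (they can never be motif instances in
        the search space anyway); if all finite scores are equal, every scored
        sequence gets weight 1 (the unweighted degenerate case).
        """
        b = self.binding_scores()
        w = np.zeros(len(b))
        fin = np.isfinite(b)
        if fin.any():
            lo, hi = b[fin].min(), b[fin].max()
            if hi > lo:
                w[fin] = (b[fin] - lo) / (hi - lo)
            else:
                w[fin] = 1.0
        return w

    def total_positions(self, width: int, mask: np.ndarray | None = None) -> int:
        """T: number of scannable window starts on both strands, over ``mask``."""
        lens = self.lengths()
        if mask is not None:
            lens = lens[np.asarray(mask, dtype=bool)]
        return int((2 * np.maximum(0, lens - width + 1)).sum())


def read_fasta(path: str | Path) -> list[ScoredSequence]:
    """Read a FASTA file into ScoredSequence records (order preserved).

    Lowercase (soft-masked) letters are uppercased; the lowercase fraction is
    kept as the repeat fraction.  Characters outside ACGTN are rejected with
    the offending record named.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header starting with '>'"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if len(raw) == 0:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        lower = sum(1 for c in raw if c.islower())
        bases = raw.upper()
        bad = set(bases) - set(_ALPHABET)
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        records.append(
            ScoredSequence(id=rec.id, bases=bases, repeat_fraction=lower / len(raw))
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[ScoredSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


def attach_scores(
    seqs: Sequence[ScoredSequence], table: str | Path
) -> Dataset:
    """Attach a 2-column TSV score table (``seq_id<TAB>score``) to sequences.

    '#'-prefixed comment lines are allowed.  Every table id must match a
    sequence id; sequences absent from the table keep ``binding_score=None``
    (treated as -inf for thresholding, i.e. permanent negative-set members).
    """
    path = Path(table)
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            sid, sval = parts
            if sid in scores:
                raise ValueError(f"{path}: line {lineno}: duplicate id {sid!r}")
            try:
                val = float(sval)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {sval!r} for {sid!r}"
                ) from None
            if not math.isfinite(val):
                raise ValueError(f"{path}: line {lineno}: non-finite score for {sid!r}")
            scores[sid] = val
    known = {s.id for s in seqs}
    unknown = sorted(set(scores) - known)
    if unknown:
        raise ValueError(f"{path}: ids not present in FASTA: {unknown[:5]}")
    out = []
    for s in seqs:
        out.append(
            ScoredSequence(
                id=s.id,
                bases=s.bases,
                binding_score=scores.get(s.id),
                is_positive_label=s.is_positive_label,
                repeat_fraction=s.repeat_fraction,
            )
        )
    return Dataset(out)


@dataclass
class MarkovBackground:
    """Order-m Markov model of the background base composition (theta_0).

    ``tables[o]`` holds, for each order o <= m, the conditional distribution
    P(base | previous o bases) as a (4**o, 4) row-stochastic array; contexts
    are base-4 codes with the oldest base most significant.  Estimated on both
    strands, so the model is strand-symmetric.  Lower-order tables provide the
    edge fallback for positions with fewer than m preceding bases.
    """

    order: int
    pseudocount: float
    tables: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (0 <= self.order <= 5):
            raise ValueError("background order must be in [0, 5]")
        for o, t in enumerate(self.tables):
            if t.shape != (4**o, 4):
                raise ValueError(f"table for order {o} has shape {t.shape}")

    @property
    def marginals(self) -> np.ndarray:
        """Order-0 base probabilities q_b."""
        return self.tables[0][0]

    @property
    def conditional_probs(self) -> dict[str, np.ndarray]:
        """Top-order conditionals keyed by context string."""
        t = self.tables[self.order]
        out = {}
        for code in range(t.shape[0]):
            ctx = ""
            c = code
            for _ in range(self.order):
                ctx = "ACGT"[c % 4] + ctx
                c //= 4
            out[ctx] = t[code]
        return out

    def flat_log_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated log tables + per-order offsets, for the scan kernels."""
        offs = np.zeros(self.order + 2, dtype=np.int64)
        parts = []
        for o, t in enumerate(self.tables):
            parts.append(np.log(t).ravel())
            offs[o + 1] = offs[o] + t.size
        return np.concatenate(parts), offs

    def log_prob(self, bases: str, pos: int, width: int, strand: str = "+") -> float:
        """log Pr(window | theta_0): reference (pure Python) implementation.

        The window is scored standalone, as a product of conditional
        probabilities in reading order: position j of the window is
        conditioned on its min(order, j) preceding window bases (shorter
        contexts at the window start).  For the minus strand the reverse
        complement of the plus-strand interval [pos, pos+width) is scored
        the same way, so palindromic windows score identically on both
        strands under this strand-symmetrized model.
        """
        if pos < 0 or pos + width > len(bases):
            raise ValueError(f"window [{pos}, {pos + width}) out of range")
        window = bases[pos : pos + width]
        if "N" in window:
            raise ValueError("window contains N")
        if strand == "-":
            window = revcomp(window)
        return sum(self.column_log_prob(window, j) for j in range(width))

    def column_log_prob(self, window: str, j: int) -> float:
        """log P(window[j] | its min(order, j) preceding window bases)."""
        oo = min(self.order, j)
        code = 0
        for t in range(oo, 0, -1):
            code = code * 4 + _ENC[window[j - t]]
        return math.log(self.tables[oo][code, _ENC[window[j]]])


def background_log_prob(
    bg: MarkovBackground, seq: str, pos: int, width: int, strand: str = "+"
) -> float:
    """log Pr(window | theta_0); see MarkovBackground.log_prob."""
    return bg.log_prob(seq, pos, width, strand)


def fit_markov_background(
    seqs: Iterable[ScoredSequence | str],
    order: int,
    pseudocount: float = 1.0,
) -> MarkovBackground:
    """Estimate conditional base probabilities of each order 0..order from
    k-mer counts on both strands, with additive smoothing.

    Contexts or bases containing N are excluded.  Warns when the data is thin
    relative to the parameter count (total length < 4**(order+1)).
    """
    if not (0 <= order <= 5):
        raise ValueError("background order must be in [0, 5]")
    strings = [s.bases if isinstance(s, ScoredSequence) else s for s in seqs]
    total_len = sum(len(s) for s in strings)
    if total_len < 4 ** (order + 1):
        warnings.warn(
            f"only {total_len} bases to fit an order-{order} background "
            f"({4 ** (order + 1)} parameters); estimates will be noisy",
            stacklevel=2,
        )
    # concatenate both strands with N separators so contexts never span records
    arrs = []
    for s in strings:
        e = encode(s)
        arrs.extend([e, np.array([4], dtype=np.int8), encode(revcomp(s)),
                     np.array([4], dtype=np.int8)])
    cat = np.concatenate(arrs)
    valid = cat < 4
    tables = []
    for o in range(order + 1):
        counts = np.full((4**o, 4), pseudocount, dtype=np.float64)
        ok = valid.copy()
        # context code with the oldest base most significant
        code = np.zeros(len(cat), dtype=np.int64)
        for t in range(o, 0, -1):
            prev = np.roll(cat, t)
            prev[:t] = 4
            ok &= prev < 4
            code = code * 4 + np.where(prev < 4, prev, 0)
        np.add.at(counts, (code[ok], cat[ok].astype(np.int64)), 1.0)
        rows = counts.sum(axis=1, keepdims=True)
        zero = rows[:, 0] == 0
        counts[zero] = 0.25  # unseen context with zero pseudocount: uniform
        rows = counts.sum(axis=1, keepdims=True)
        tables.append(counts / rows)
    return MarkovBackground(order=order, pseudocount=pseudocount, tables=tables)


# ---------------------------------------------------------------------------
# matched negative sets


def klet_shuffle(seq: str, k: int, rng: np.random.Generator) -> str:
    """Order-preserving k-let shuffle (Altschul-Erickson).

    Returns a permutation of ``seq`` with exactly the same k-let (and hence
    all shorter-let) counts.  For k=1 this is a plain letter shuffle.  N is
    treated as a fifth symbol, so masked content is preserved too.
    """
    n = len(seq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        chars = list(seq)
        rng.shuffle(chars)
        return "".join(chars)
    if n <= k:
        return seq
    # vertices are (k-1)-lets; edges are the n-k+1 observed transitions
    verts = [seq[i : i + k - 1] for i in range(n - k + 2)]
    start, end = verts[0], verts[-1]
    out_edges: dict[str, list[str]] = {}
    for i in range(len(verts) - 1):
        out_edges.setdefault(verts[i], []).append(verts[i + 1])
    vset = list(out_edges.keys())
    if end not in out_edges:
        out_edges[end] = []
        vset.append(end)
    # pick a random last-edge per vertex (except end) forming an arborescence
    # toward end; rejection sampling is fast for these small graphs
    for _attempt in range(10000):
        last = {}
        for v in vset:
            if v == end or not out_edges[v]:
                continue
            last[v] = out_edges[v][rng.integers(len(out_edges[v]))]
        ok = True
        for v in last:
            # walk the last-edge chain; must reach end without cycling
            seen = {v}
            cur = v
            while cur != end:
                if cur not in last:
                    ok = False
                    break
                cur = last[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection sampling virtually always succeeds
        return seq
    walk_edges = {}
    for v in vset:
        edges = list(out_edges[v])
        if v in last:
            edges.remove(last[v])
        rng.shuffle(edges)
        if v in last:
            edges.append(last[v])
        walk_edges[v] = edges
    pieces = [start]
    cur = start
    ptr = {v: 0 for v in vset}
    for _ in range(len(verts) - 1):
        nxt = walk_edges[cur][ptr[cur]]
        ptr[cur] += 1
        pieces.append(nxt[-1])
        cur = nxt
    return "".join(pieces)


def generate_matched_negatives(
    positives: Dataset,
    pool: str | Dataset = "shuffle",
    ratio: int = 2,
    k: int = 2,
    rng: np.random.Generator | None = None,
    gc_tol: float = 0.025,
    repeat_tol: float = 0.10,
    len_tol: float = 0.05,
) -> Dataset:
    """Build a negative set matched in length, GC and repeat fraction.

    In ``"shuffle"`` mode each positive contributes ``ratio`` order-preserving
    k-let shuffles of itself (k = background order + 1 is the usual choice),
    which match composition by construction.  In pool mode, negatives are
    drawn without replacement from a genomic pool within matching tolerance
    bins (GC within +-2.5 %, repeat fraction within +-10 %, length within
    +-5 %), relaxing the tolerances stepwise with a warning when a bin is
    exhausted.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    negatives: list[ScoredSequence] = []
    if isinstance(pool, str) and pool == "shuffle":
        for s in positives:
            for r in range(ratio):
                negatives.append(
                    ScoredSequence(
                        id=f"{s.id}|shuffle{r + 1}",
                        bases=klet_shuffle(s.bases, k, rng),
                        binding_score=None,
                        is_positive_label=False,
                        repeat_fraction=s.repeat_fraction,
                    )
                )
        return Dataset(negatives)
    pool_seqs = list(pool)
    used = np.zeros(len(pool_seqs), dtype=bool)
    gcs = np.array([p.gc for p in pool_seqs])
    reps = np.array([p.repeat_fraction for p in pool_seqs])
    lens = np.array([len(p) for p in pool_seqs], dtype=float)
    for s in positives:
        for r in range(ratio):
            scale = 1.0
            while True:
                cand = np.flatnonzero(
                    (~used)
                    & (np.abs(gcs - s.gc) <= gc_tol * scale)
                    & (np.abs(reps - s.repeat_fraction) <= repeat_tol * scale)
                    & (np.abs(lens - len(s)) <= len_tol * scale * len(s))
                )
                if len(cand):
                    break
                scale *= 1.5
                if scale > 100:
                    raise ValueError("negative pool exhausted even after relaxation")
                warnings.warn(
                    f"pool bin exhausted for {s.id!r}; relaxing tolerances x{scale:.1f}",
                    stacklevel=2,
                )
            j = int(cand[rng.integers(len(cand))])
            used[j] = True
            p = pool_seqs[j]
            negatives.append(
                ScoredSequence(
                    id=f"{p.id}|neg",
                    bases=p.bases,
                    binding_score=None,
                    is_positive_label=False,
                    repeat_fraction=p.repeat_fraction,
                )
            )
    return Dataset(negatives)
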