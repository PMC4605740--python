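"""Synthetic benchmark generators and recovery scoring.

Two generators: a planted-motif ChIP-like fixture (positives carrying one
sampled instance of a known PWM plus elevated binding scores, negatives pure
background), and a sequence-expression benchmark emulating intergenic
regions of a compact genome: background sequences at intergenic GC content,
ubiquitous "decoy" motifs seeded into every sequence (over-represented but
not specific), and "functional" motifs seeded only into the members of
co-expressed gene sets whose expression follows one of two anti-correlated
programs (stress induction / repression).  Ground truth is retained so that
reported motifs can be scored for precision and recall of recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprmode import ExpressionMatrix
from .pwm import GappedPWM, compareace_similarity
from .search import MotifArchive
from .seqio import Dataset, ScoredSequence

__all__ = [
    "SynthExprConfig",
    "PlantedMotif",
    "GroundTruth",
    "make_chip_fixture",
    "make_expression_fixture",
    "score_recovery",
    "recall_at_precision",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedMotif:
    name: str
    pwm: GappedPWM
    members: list[str]  # gene/sequence ids carrying an instance
    program: str  # "induced", "repressed", "decoy", or "chip"

    @property
    def consensus(self) -> str:
        return self.pwm.consensus


@dataclass
class GroundTruth:
    functional: list[PlantedMotif]
    decoys: list[PlantedMotif] = field(default_factory=list)
    # per sequence id: list of (motif name, pos, strand) actually planted
    instances: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    program_mean_correlation: float | None = None


@dataclass
class SynthExprConfig:
    """Study conditions of the sequence-expression benchmark.

    Defaults describe the full-scale benchmark: 5000 sequences with Gaussian
    lengths (mean 800 bp, sd 100 bp) at intergenic-like GC 0.38, four decoy
    motifs seeded into every sequence, and 80 functional motifs (half per
    expression program) seeded one instance per member of its co-expressed
    gene set.
    """

    n_sequences: int = 5000
    length_mean: float = 800.0
    length_sd: float = 100.0
    gc_content: float = 0.38
    n_functional: int = 80
    n_decoys_per_seq: int = 4
    member_min: int = 20
    member_max: int = 200
    n_conditions: int = 50
    noise_sd: float = 0.8
    program_fraction: float = 0.8  # genes assignable to the two programs
    motif_len_min: int = 8
    motif_len_max: int = 12
    n_degenerate: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sequences", "n_functional", "n_decoys_per_seq",
                     "member_min", "member_max", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.member_max > self.n_sequences:
            raise ValueError("member sets cannot exceed the number of sequences")


def _random_motif(rng: np.random.Generator, length: int, n_degenerate: int) -> GappedPWM:
    """A random planted motif: sharp consensus with a couple of degenerate
    (two-base) positions, as a contiguous PWM."""
    freqs = np.full((length, 4), 0.03)
    for j in range(length):
        freqs[j, rng.integers(4)] = 0.91
    deg = rng.choice(length, size=min(n_degenerate, length), replace=False)
    for j in deg:
        b1, b2 = rng.choice(4, size=2, replace=False)
        freqs[j] = 0.05
        freqs[j, b1] = 0.45
        freqs[j, b2] = 0.45
    freqs /= freqs.sum(axis=1, keepdims=True)
    return GappedPWM(length, np.arange(length), freqs)


def _sample_instance(pwm: GappedPWM, rng: np.random.Generator) -> str:
    out = []
    for row in pwm.freqs:
        out.append(str(rng.choice(_BASES, p=row)))
    return "".join(out)


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _plant(seq: list, instance: str, pos: int, strand: str) -> None:
    from .seqio import revcomp

    s = instance if strand == "+" else revcomp(instance)
    seq[pos : pos + len(s)] = list(s)


def make_chip_fixture(
    n_pos: int,
    n_neg: int,
    seq_len: int,
    planted_pwm: GappedPWM,
    plant_frac: float = 0.8,
    bg_gc: float = 0.41,
    seed: int = 0,
) -> tuple[Dataset, GroundTruth]:
    """ChIP-like fixture: positives carry one PWM-sampled instance at a
    uniform random position/strand in ``plant_frac`` of them, with binding
    scores drawn from a higher Gaussian for planted sequences; negatives are
    pure background with low scores."""
    if not (0 <= plant_frac <= 1):
        raise ValueError("plant_frac must be in [0, 1]")
    W = planted_pwm.window_width
    if W > seq_len:
        raise ValueError("planted motif wider than the sequences")
    rng = np.random.default_rng(seed)
    seqs: list[ScoredSequence] = []
    planted_ids: list[str] = []
    instances: dict[str, list[tuple[str, int, str]]] = {}
    planted = np.zeros(n_pos, dtype=bool)
    planted[rng.choice(n_pos, size=int(round(plant_frac * n_pos)), replace=False)] = True
    for i in range(n_pos):
        sid = f"pos{i:04d}"
        chars = list(_background(rng, seq_len, bg_gc))
        if planted[i]:
            pos = int(rng.integers(seq_len - W + 1))
            strand = "+-"[rng.integers(2)]
            _plant(chars, _sample_instance(planted_pwm, rng), pos, strand)
            planted_ids.append(sid)
            instances[sid] = [("planted", pos, strand)]
            score = float(rng.normal(4.0, 1.0))
        else:
            score = float(rng.normal(2.0, 1.0))
        seqs.append(ScoredSequence(sid, "".join(chars), binding_score=score,
                                   is_positive_label=True))
    for i in range(n_neg):
        seqs.append(
            ScoredSequence(
                f"neg{i:04d}", _background(rng, seq_len, bg_gc),
                binding_score=float(rng.normal(0.0, 1.0)),
                is_positive_label=False,
            )
        )
    truth = GroundTruth(
        functional=[PlantedMotif("planted", planted_pwm, planted_ids, "chip")],
        instances=instances,
    )
    return Dataset(seqs), truth


def make_expression_fixture(
    cfg: SynthExprConfig,
) -> tuple[Dataset, ExpressionMatrix, GroundTruth]:
    """The sequence-expression benchmark (see module docstring).

    Returns upstream sequences, the gene-by-condition expression matrix, and
    the ground truth (functional motifs with their member sets and programs,
    decoy motifs, and every planted instance).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_sequences
    ids = [f"g{i:05d}" for i in range(n)]
    min_len = 2 * cfg.motif_len_max
    lengths = np.maximum(
        min_len, np.round(rng.normal(cfg.length_mean, cfg.length_sd, n)).astype(int)
    )
    seq_chars = [list(_background(rng, int(L), cfg.gc_content)) for L in lengths]
    instances: dict[str, list[tuple[str, int, str]]] = {sid: [] for sid in ids}

    # decoy motifs: seeded into every sequence, hence over-represented
    # everywhere but specific to nothing
    decoys = []
    for d in range(cfg.n_decoys_per_seq):
        L = int(rng.integers(cfg.motif_len_min, cfg.motif_len_max + 1))
        decoys.append(PlantedMotif(f"decoy{d}", _random_motif(rng, L, cfg.n_degenerate),
                                   list(ids), "decoy"))
    for i, sid in enumerate(ids):
        for d in decoys:
            W = d.pwm.window_width
            pos = int(rng.integers(lengths[i] - W + 1))
            strand = "+-"[rng.integers(2)]
            _plant(seq_chars[i], _sample_instance(d.pwm, rng), pos, strand)
            instances[sid].append((d.name, pos, strand))

    # two anti-correlated expression programs
    n_prog = int(round(cfg.program_fraction * n / 2))
    perm = rng.permutation(n)
    induced_pool = perm[:n_prog]
    repressed_pool = perm[n_prog : 2 * n_prog]
    pattern = rng.standard_normal(cfg.n_conditions)
    pattern = (pattern - pattern.mean()) / pattern.std()
    means = {"induced": pattern, "repressed": -pattern}
    corr = float(np.corrcoef(means["induced"], means["repressed"])[0, 1])

    # functional motifs: one instance per member of a co-expressed gene set
    functional = []
    half = cfg.n_functional // 2
    for m in range(cfg.n_functional):
        program = "induced" if m < half else "repressed"
        pool = induced_pool if program == "induced" else repressed_pool
        L = int(rng.integers(cfg.motif_len_min, cfg.motif_len_max + 1))
        pwm = _random_motif(rng, L, cfg.n_degenerate)
        size = int(round(math.exp(rng.uniform(math.log(cfg.member_min),
                                              math.log(cfg.member_max)))))
        size = min(size, len(pool))
        members_idx = rng.choice(pool, size=size, replace=False)
        members = []
        for gi in members_idx:
            gi = int(gi)
            sid = ids[gi]
            W = pwm.window_width
            pos = int(rng.integers(lengths[gi] - W + 1))
            strand = "+-"[rng.integers(2)]
            _plant(seq_chars[gi], _sample_instance(pwm, rng), pos, strand)
            instances[sid].append((f"func{m}", pos, strand))
            members.append(sid)
        functional.append(PlantedMotif(f"func{m}", pwm, members, program))

    # expression: members of functional motifs follow their program mean,
    # everything else is flat noise
    member_program = {}
    for f in functional:
        for sid in f.members:
            member_program[sid] = f.program
    values = np.empty((n, cfg.n_conditions))
    for i, sid in enumerate(ids):
        mean = means.get(member_program.get(sid), np.zeros(cfg.n_conditions))
        values[i] = mean + rng.normal(0.0, cfg.noise_sd, cfg.n_conditions)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=ids,
                     columns=[f"cond{c:03d}" for c in range(cfg.n_conditions)])
    )
    seqs = Dataset(
        [ScoredSequence(sid, "".join(ch)) for sid, ch in zip(ids, seq_chars)]
    )
    truth = GroundTruth(
        functional=functional, decoys=decoys, instances=instances,
        program_mean_correlation=corr,
    )
    return seqs, expr, truth


def score_recovery(
    archive: MotifArchive,
    truth: GroundTruth,
    sim_threshold: float = 0.75,
) -> pd.DataFrame:
    """Precision/recall of planted-motif recovery at every archive cutoff.

    Reported motifs are matched one-to-one to functional planted motifs,
    greedily by descending CompareACE similarity, requiring similarity at or
    above ``sim_threshold``; a motif reported twice counts once (the second
    report is a false positive).  Rows follow the archive's score order;
    ``precision``/``recall`` are cumulative down the ranking.
    """
    reports = list(archive)
    n_truth = len(truth.functional)
    if not reports:
        return pd.DataFrame(
            columns=["score", "matched_truth", "precision", "recall"]
        )
    sims = np.array(
        [
            [compareace_similarity(r.pwm, t.pwm) for t in truth.functional]
            for r in reports
        ]
    )
    cands = sorted(
        ((i, j) for i in range(len(reports)) for j in range(n_truth)
         if sims[i, j] >= sim_threshold),
        key=lambda ij: (-sims[ij], ij[0], ij[1]),
    )

    def match_prefix(k: int):
        """Greedy one-to-one matching (descending similarity, ties toward
        the better-scoring report) among the top-k reports only."""
        used_r, used_t = set(), set()
        names = [None] * k
        for i, j in cands:
            if i >= k or i in used_r or j in used_t:
                continue
            used_r.add(i)
            used_t.add(j)
            names[i] = truth.functional[j].name
        return names

    # precision/recall at each archive-score cutoff: matching is recomputed
    # within the reported prefix, so a report below the cutoff can never
    # claim a planted motif away from one above it
    precision = np.empty(len(reports))
    recall = np.empty(len(reports))
    for k in range(1, len(reports) + 1):
        tp = sum(m is not None for m in match_prefix(k))
        precision[k - 1] = tp / k
        recall[k - 1] = tp / n_truth
    return pd.DataFrame(
        {
            "score": [r.score for r in reports],
            "matched_truth": match_prefix(len(reports)),
            "precision": precision,
            "recall": recall,
        }
    )


def recall_at_precision(table: pd.DataFrame, min_precision: float = 0.9) -> float:
    """Highest recall achieved at any archive-score cutoff whose cumulative
    precision is at least ``min_precision`` (0 when none qualifies)."""
    if len(table) == 0:
        return 0.0
    ok = table["precision"] >= min_precision
    if not ok.any():
        return 0.0
    return float(table.loc[ok, "recall"].max())
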