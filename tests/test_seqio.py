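"""Sequence I/O, Markov backgrounds, and matched negative sets."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specmotif.seqio import (
    Dataset,
    ScoredSequence,
    attach_scores,
    background_log_prob,
    fit_markov_background,
    generate_matched_negatives,
    klet_shuffle,
    read_fasta,
    revcomp,
)


class TestReadFasta:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nACGT\n>b\nGG\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert [len(r) for r in recs] == [4, 2]

    def test_lowercase_uppercased_with_repeat_fraction(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nacgt\n>b\nACgt\n")
        recs = read_fasta(p)
        assert recs[0].bases == "ACGT" and recs[0].repeat_fraction == 1.0
        assert recs[1].bases == "ACGT" and recs[1].repeat_fraction == 0.5

    def test_invalid_character_names_record(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">good\nACGT\n>bad\nACXT\n")
        with pytest.raises(ValueError, match="bad"):
            read_fasta(p)

    def test_missing_header_names_line(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)


class TestAttachScores:
    def _seqs(self):
        return [
            ScoredSequence("a", "ACGT"),
            ScoredSequence("b", "ACGT"),
            ScoredSequence("c", "ACGT"),
        ]

    def test_partial_table(self, tmp_path):
        t = tmp_path / "s.tsv"
        t.write_text("# comment\na\t5.0\nb\t1.0\n")
        ds = attach_scores(self._seqs(), t)
        assert ds["a"].binding_score == 5.0
        assert ds["b"].binding_score == 1.0
        assert ds["c"].binding_score is None
        assert ds.binding_scores()[2] == -math.inf

    def test_binary_labels_as_scores(self, tmp_path):
        t = tmp_path / "s.tsv"
        t.write_text("a\t1\nb\t0\nc\t0\n")
        ds = attach_scores(self._seqs(), t)
        assert list(ds.binding_scores()) == [1.0, 0.0, 0.0]

    def test_unknown_id_rejected(self, tmp_path):
        t = tmp_path / "s.tsv"
        t.write_text("zz\t5.0\n")
        with pytest.raises(ValueError, match="zz"):
            attach_scores(self._seqs(), t)

    def test_duplicate_and_non_numeric_rejected(self, tmp_path):
        t = tmp_path / "s.tsv"
        t.write_text("a\t5.0\na\t6.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            attach_scores(self._seqs(), t)
        t.write_text("a\tfive\n")
        with pytest.raises(ValueError, match="non-numeric"):
            attach_scores(self._seqs(), t)


class TestMarkovBackground:
    def test_order0_uniform(self):
        bg = fit_markov_background(["ACGT"], 0, pseudocount=0.0)
        assert np.allclose(bg.marginals, 0.25)

    def test_order1_degenerate_chain(self):
        bg = fit_markov_background(["AAAA"], 1, pseudocount=0.0)
        # both strands: AAAA + TTTT; P(A|A)=1, P(T|T)=1
        assert bg.conditional_probs["A"][0] == pytest.approx(1.0)
        assert bg.conditional_probs["T"][3] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        bg = fit_markov_background(["ACGTTGCAACGT" * 30], 3)
        for t in bg.tables:
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_order3_recovery_from_simulated_chain(self):
        # simulate a long sequence from a known 3rd-order chain and check
        # the fitted conditionals recover it
        rng = np.random.default_rng(0)
        true = rng.dirichlet(np.full(4, 5.0), size=64)  # (4^3, 4)
        seq = list(np.array(list("ACG"))[[0, 1, 2]])
        codes = {c: i for i, c in enumerate("ACGT")}
        state = [0, 1, 2]
        out = ["A", "C", "G"]
        for _ in range(100_000):
            ctx = state[0] * 16 + state[1] * 4 + state[2]
            b = int(rng.choice(4, p=true[ctx]))
            out.append("ACGT"[b])
            state = state[1:] + [b]
        # fit on one strand only by symmetrizing the truth is messy; instead
        # compare against the strand-averaged truth via the fitted model's
        # plus-strand predictions on a fresh simulation: simpler and robust is
        # to fit with both strands and check plus-strand conditionals of a
        # palindromic-symmetric construction; here we just check the fitted
        # conditionals on the forward strand dominate within +-0.02 after
        # symmetrization
        s = "".join(out)
        bg = fit_markov_background([s], 3, pseudocount=1.0)
        # the fitted table is the average of the true chain and its reverse
        # complement image; verify the fitted probabilities match empirical
        # forward+reverse counts within 0.02
        emp = np.full((64, 4), 0.0)
        for strand in (s, revcomp(s)):
            for i in range(3, len(strand)):
                ctx = (
                    codes[strand[i - 3]] * 16
                    + codes[strand[i - 2]] * 4
                    + codes[strand[i - 1]]
                )
                emp[ctx, codes[strand[i]]] += 1
        emp = emp / emp.sum(axis=1, keepdims=True)
        assert np.abs(bg.tables[3] - emp).max() < 0.02

    def test_order_bounds(self):
        with pytest.raises(ValueError):
            fit_markov_background(["ACGT"], 6)


class TestBackgroundLogProb:
    def test_order0_uniform_window(self, uniform_bg):
        v = background_log_prob(uniform_bg, "ACGTACGT", 2, 3, "+")
        assert v == pytest.approx(3 * math.log(0.25), abs=1e-9)

    def test_palindrome_strand_symmetry(self):
        bg = fit_markov_background(["ACGTTAGCAGCTAAGC" * 20], 2)
        # palindromic window: plus and minus scores must agree because the
        # model is strand-symmetrized
        seq = "AAGAATTCAA"
        plus = background_log_prob(bg, seq, 3, 4, "+")  # AATT
        minus = background_log_prob(bg, seq, 3, 4, "-")
        assert plus == pytest.approx(minus, rel=1e-9)

    def test_edge_fallback_uses_shorter_context(self):
        bg = fit_markov_background(["ACGGTACCAGTTACA" * 10], 2)
        # window at pos 0: P(A) * P(C|A) * P(G|AC)
        want = (
            math.log(bg.tables[0][0, 1 - 1])
            + math.log(bg.tables[1][0, 1])
            + math.log(bg.tables[2][0 * 4 + 1, 2])
        )
        got = background_log_prob(bg, "ACGGTACCAGT", 0, 3, "+")
        assert got == pytest.approx(want, abs=1e-12)

    def test_chain_rule_on_order0(self, uniform_bg):
        seq = "ACGTACGTAC"
        whole = background_log_prob(uniform_bg, seq, 0, 10)
        parts = background_log_prob(uniform_bg, seq, 0, 4) + background_log_prob(
            uniform_bg, seq, 4, 6
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_out_of_range_window(self, uniform_bg):
        with pytest.raises(ValueError):
            background_log_prob(uniform_bg, "ACGT", 2, 5)


class TestKletShuffle:
    @given(
        st.text(alphabet="ACGT", min_size=5, max_size=60),
        st.integers(1, 3),
        st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_klet_counts_preserved(self, seq, k, seed):
        rng = np.random.default_rng(seed)
        shuf = klet_shuffle(seq, k, rng)
        assert len(shuf) == len(seq)
        for kk in range(1, k + 1):
            want = Counter(seq[i : i + kk] for i in range(len(seq) - kk + 1))
            got = Counter(shuf[i : i + kk] for i in range(len(shuf) - kk + 1))
            assert want == got

    def test_shuffles_actually_change_order(self):
        rng = np.random.default_rng(1)
        seq = "ACGTGCATTGCAACGTAGCTAGCTTACG" * 4
        assert any(klet_shuffle(seq, 2, rng) != seq for _ in range(5))


class TestMatchedNegatives:
    def test_shuffle_mode_counts_and_gc(self):
        pos = Dataset(
            [ScoredSequence(f"p{i}", "ACGTTGCA" * 8) for i in range(10)]
        )
        neg = generate_matched_negatives(pos, "shuffle", ratio=2, k=2,
                                         rng=np.random.default_rng(0))
        assert len(neg) == 20
        for n in neg:
            assert n.gc == pytest.approx(0.5)

    def test_ratio_four(self):
        pos = Dataset([ScoredSequence(f"p{i}", "ACGTTGCA" * 4) for i in range(5)])
        neg = generate_matched_negatives(pos, "shuffle", ratio=4,
                                         rng=np.random.default_rng(0))
        assert len(neg) == 4 * len(pos)

    def test_ratio_below_one_rejected(self):
        pos = Dataset([ScoredSequence("p", "ACGT" * 5)])
        with pytest.raises(ValueError):
            generate_matched_negatives(pos, "shuffle", ratio=0)

    def test_pool_mode_matches_gc(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        def mk(gc, n, tag):
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            return [
                ScoredSequence(f"{tag}{i}", "".join(rng.choice(bases, 100, p=p)))
                for i in range(n)
            ]
        pos = Dataset(mk(0.45, 15, "p"))
        pool = Dataset(mk(0.30, 150, "q") + mk(0.45, 150, "r") + mk(0.60, 150, "s"))
        neg = generate_matched_negatives(pos, pool, ratio=2,
                                         rng=np.random.default_rng(5))
        mean_pos = np.mean([s.gc for s in pos])
        mean_neg = np.mean([s.gc for s in neg])
        assert abs(mean_pos - mean_neg) < 0.02
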