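"""Alignment engine, orientation normalization and the two accuracy metrics.

The affine-gap score of ``global_align`` is checked against an independent
Gotoh dynamic program written here from the recurrences, on exhaustively
small random sequences.
"""

import numpy as np
import pytest

from mitobench.circular_align import (
    AlignmentResult,
    AnchorNotFoundError,
    completeness,
    global_align,
    normalize_orientation,
    p_distance,
)
from mitobench.seq_core import CircularGenome, NucSequence, revcomp, rotate
from mitobench.synthetic_data import GenomeSpec, make_genome

N = lambda b: NucSequence(id="x", bases=b)  # noqa: E731

NEG = -(10.0**9)


def gotoh_score(a, b, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Reference affine-gap global alignment score (gap of length L costs
    |gap_open| + |gap_extend|*L), straight from the three-state recurrence."""
    la, lb = len(a), len(b)
    open_cost = gap_open + gap_extend  # first gap base pays open + extend
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (deletion)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (insertion)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = open_cost + gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = open_cost + gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + gap_extend)
    return max(M[la][lb], X[la][lb], Y[la][lb])


class TestGlobalAlign:
    def test_identical(self):
        a = global_align(N("ACGT"), N("ACGT"))
        assert a.aligned_ref == a.aligned_qry == "ACGT"
        assert a.score == 8.0

    def test_single_gap_against_reference_base(self):
        a = global_align(N("ACGT"), N("AGT"))
        assert a.aligned_ref == "ACGT" and a.aligned_qry == "A-GT"

    def test_gap_left_shifted_in_homopolymer(self):
        a = global_align(N("AAAAA"), N("AAAA"))
        assert a.aligned_qry == "-AAAA"

    @pytest.mark.parametrize("trial", range(20))
    def test_score_matches_gotoh_oracle_on_short_sequences(self, trial):
        rng = np.random.default_rng(trial)
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
        aln = global_align(N(a), N(b), method="affine")
        assert aln.score == gotoh_score(a, b)

    def test_degap_reproduces_inputs(self):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = a[:100] + a[120:250] + "TTTT" + a[250:]
        for method in ("affine", "edit"):
            aln = global_align(N(a), N(b), method=method)
            assert aln.ref == a and aln.qry == b

    def test_engines_agree_on_near_identical_sequences(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(list("ACGT"), size=600))
        lst = list(a)
        lst[200] = "A" if lst[200] != "A" else "C"
        del lst[400]
        b = "".join(lst)
        fast = global_align(N(a), N(b), method="edit")
        exact = global_align(N(a), N(b), method="affine")
        assert fast.score == exact.score
        assert fast.aligned_ref == exact.aligned_ref

    def test_no_gap_in_both_columns(self):
        aln = global_align(N("ACGTACGT"), N("AGTACGGT"))
        assert all(
            not (r == "-" and q == "-")
            for r, q in zip(aln.aligned_ref, aln.aligned_qry)
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            AlignmentResult(aligned_ref="A-", aligned_qry="--")


class TestPDistance:
    def test_identical_is_zero(self):
        assert p_distance(global_align(N("ACGTAC"), N("ACGTAC"))) == 0.0

    def test_one_mismatch_in_four(self):
        assert p_distance(global_align(N("ACGT"), N("ACCT"))) == 0.25

    def test_gaps_excluded_pairwise_deletion(self):
        # substitutions count, indels do not
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=2000))
        lst = list(a)
        for pos in (100, 500, 900, 1500):
            lst[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[lst[pos]]
        for pos in (1800, 1200, 700):  # delete from the right to keep coords
            del lst[pos]
        b = "".join(lst)
        aln = global_align(N(a), N(b))
        assert p_distance(aln) == pytest.approx(4 / (2000 - 3))

    def test_symmetry(self):
        a, b = "ACGTTGCA", "ACCTTGGA"
        assert p_distance(global_align(N(a), N(b))) == p_distance(
            global_align(N(b), N(a))
        )

    def test_all_gap_columns_error(self):
        aln = AlignmentResult(aligned_ref="A-", aligned_qry="-C")
        with pytest.raises(ValueError):
            p_distance(aln)


class TestCompleteness:
    def test_full_identity(self):
        s = N("ACGTACGTAC")
        assert completeness(s, s, global_align(s, s)) == 1.0

    def test_half_reference(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), size=400))
        half = a[:200]
        aln = global_align(N(a), N(half))
        assert completeness(N(a), N(half), aln) == pytest.approx(0.5)


class TestNormalizeOrientation:
    def test_rotation_recovery(self, genome):
        q = rotate(genome, 500)
        assert normalize_orientation(genome, q).bases == genome.bases

    def test_strand_and_rotation_recovery(self, genome):
        q = CircularGenome(seq=revcomp(rotate(genome, 500).seq), circular=True)
        assert normalize_orientation(genome, q).bases == genome.bases

    def test_mutated_rotation_recovers_frame(self):
        g, _ = make_genome(GenomeSpec(seed=17))
        rng = np.random.default_rng(1)
        lst = list(g.bases)
        for pos in rng.choice(np.arange(200, len(lst) - 200), 10, replace=False):
            lst[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[lst[pos]]
        mut = CircularGenome(seq=NucSequence(id="m", bases="".join(lst)))
        q = rotate(mut, 137)
        qn = normalize_orientation(g, q)
        aln = global_align(g.seq, qn.seq)
        assert p_distance(aln) == pytest.approx(10 / len(g))

    def test_no_anchor_errors(self):
        a = CircularGenome(seq=N("ACGT" * 20))
        b = CircularGenome(seq=N("TTTTGGGG" * 10))
        with pytest.raises(AnchorNotFoundError):
            normalize_orientation(a, b)
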