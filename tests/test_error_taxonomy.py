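"""Error extraction, homopolymer-aware classification and benchmarking."""

import numpy as np
import pytest

from mitobench.circular_align import AlignmentResult, global_align
from mitobench.error_taxonomy import (
    ErrorEvent,
    benchmark,
    benchmark_genomes,
    classify_event,
    extract_events,
    summarize,
)
from mitobench.seq_core import (
    CircularGenome,
    NucSequence,
    revcomp,
    rotate,
    write_fasta,
)
from mitobench.synthetic_data import (
    ErrorProfile,
    GenomeSpec,
    inject_errors,
    make_genome,
    random_error_profile,
)

N = lambda b: NucSequence(id="x", bases=b)  # noqa: E731


class TestExtractEvents:
    def test_perfect_alignment_yields_nothing(self):
        aln = global_align(N("ACGTACGT"), N("ACGTACGT"))
        assert extract_events(aln) == []

    def test_indel_plus_mismatches(self):
        aln = AlignmentResult(
            aligned_ref="A-CGTACGT", aligned_qry="ATCGTAGTA"
        )
        events = extract_events(aln)
        cats = [e.category for e in events]
        assert cats == ["single_insertion"] + ["simple_substitution"] * 3

    def test_adjacent_gap_columns_group_into_one_event(self):
        aln = AlignmentResult(aligned_ref="ACGTAC", aligned_qry="AC--AC")
        events = extract_events(aln)
        assert len(events) == 1
        assert events[0].size == 2 and events[0].ref_bases == "GT"

    def test_mismatch_run_splits_into_unit_substitutions(self):
        aln = AlignmentResult(aligned_ref="AAAA", aligned_qry="ACCA")
        events = extract_events(aln)
        assert [e.size for e in events] == [1, 1]
        assert [e.ref_pos for e in events] == [2, 3]


class TestClassifyEvent:
    def _event(self, kind, pos, ref_bases="", qry_bases=""):
        cat = {
            "ins": "single_insertion" if len(qry_bases) == 1 else "short_insertion",
            "del": "single_deletion" if len(ref_bases) == 1 else "short_deletion",
        }[kind]
        return ErrorEvent(
            category=cat,
            size=max(len(ref_bases), len(qry_bases)),
            ref_pos=pos,
            ref_bases=ref_bases,
            qry_bases=qry_bases,
        )

    def test_deletion_in_long_t_homopolymer(self):
        # one T removed from an 11-bp T run
        ref = N("GC" + "T" * 11 + "GC")
        e = self._event("del", 3, ref_bases="T")
        out = classify_event(e, ref, N(ref.bases[:2] + "T" * 10 + "GC"))
        assert out.category == "homopolymer_deletion"
        assert out.multiplicity_label == "single"
        assert out.homopolymer_base == "T"

    def test_insertion_next_to_a_homopolymer(self):
        # one A added beside a 5-bp A run
        ref = N("GC" + "A" * 5 + "GC")
        e = self._event("ins", 3, qry_bases="A")
        out = classify_event(e, ref, N("GC" + "A" * 6 + "GC"))
        assert out.category == "homopolymer_insertion"
        assert out.multiplicity_label == "single"

    def test_run_shorter_than_min_run_stays_short_insertion(self):
        # "GG" inserted next to a single G: run length 1 < 2
        ref = N("ATGAT")
        e = self._event("ins", 3, qry_bases="GG")
        out = classify_event(e, ref, N("ATGGGAT"))
        assert out.category == "short_insertion"

    def test_mixed_base_indel_never_homopolymer(self):
        ref = N("GC" + "A" * 5 + "GC")
        e = self._event("ins", 3, qry_bases="AT")
        out = classify_event(e, ref, N("GCAT" + "A" * 5 + "GC"))
        assert out.category == "short_insertion"

    def test_tandem_duplication_flag_14bp_motif(self):
        motif = "AATGTTCTGGTGGG"
        ref = N("CCCC" + motif + "ACAC")
        qry = N("CCCC" + motif + motif + "ACAC")
        e = self._event("ins", 5, qry_bases=motif)
        out = classify_event(e, ref, qry)
        assert out.category == "short_insertion"
        assert out.tandem_duplication and out.size == 14

    def test_multiplicity_labels(self):
        ref = N("GC" + "T" * 12 + "GC")
        for size, label in [(2, "double"), (7, "septuple"), (8, "gt7")]:
            e = self._event("del", 3, ref_bases="T" * size)
            out = classify_event(e, ref, N("GC" + "T" * (12 - size) + "GC"))
            assert out.category == "homopolymer_deletion"
            assert out.multiplicity_label == label

    def test_classification_idempotent(self):
        ref = N("GC" + "T" * 11 + "GC")
        e = self._event("del", 3, ref_bases="T")
        once = classify_event(e, ref, N("GC" + "T" * 10 + "GC"))
        twice = classify_event(once, ref, N("GC" + "T" * 10 + "GC"))
        assert once == twice

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_event(self._event("del", 99, ref_bases="T"), N("ACGT"), N("ACG"))


class TestSummarize:
    def test_empty(self):
        s = summarize([])
        assert s.total_errors == 0 and all(v == 0 for v in s.counts.values())

    def test_mixed_tally(self):
        events = [
            ErrorEvent("simple_substitution", 1, 5, "A", "C"),
            ErrorEvent("simple_substitution", 1, 9, "G", "T"),
            ErrorEvent("simple_substitution", 1, 14, "G", "A"),
            ErrorEvent(
                "homopolymer_insertion", 1, 20, "", "T",
                multiplicity_label="single", homopolymer_base="T",
            ),
            ErrorEvent(
                "homopolymer_insertion", 1, 40, "", "A",
                multiplicity_label="single", homopolymer_base="A",
            ),
        ]
        s = summarize(events)
        assert s.total_errors == 5
        assert s.counts["simple_substitution"] == 3
        assert s.multiplicities["homopolymer_insertion"] == {"single": 2}


class TestBenchmark:
    def test_identity_query(self, genome):
        rep = benchmark_genomes(genome, rotate(genome, 777))
        assert rep.p_distance == 0.0
        assert rep.error_summary.total_errors == 0
        assert rep.total_length == len(genome)
        assert rep.completeness == 1.0

    def test_extra_tandem_copy_is_one_event(self):
        g, man = make_genome(GenomeSpec(length=16498, seed=9))
        mut, truth = inject_errors(g, ErrorProfile(tandem_duplications=(14,), seed=4), man)
        rep = benchmark_genomes(g, mut)
        assert rep.total_length == len(g) + 14
        assert rep.error_summary.total_errors == 1
        assert sum(e.tandem_duplication for e in rep.events) == 1

    def test_ten_seeded_substitutions(self, genome, manifest):
        prof = ErrorProfile(simple_substitution=10, seed=21)
        mut, truth = inject_errors(genome, prof, manifest)
        rep = benchmark_genomes(genome, mut)
        assert rep.error_summary.counts["simple_substitution"] == 10
        assert rep.p_distance == pytest.approx(10 / len(genome))

    def test_total_errors_invariant_under_rotation_and_strand(self, genome, manifest):
        prof = random_error_profile(genome, 20, seed=5, manifest=manifest)
        mut, _ = inject_errors(genome, prof, manifest)
        base = benchmark_genomes(genome, mut)
        rng = np.random.default_rng(8)
        for _ in range(4):
            q = rotate(mut, int(rng.integers(1, len(mut))))
            if rng.random() < 0.5:
                q = CircularGenome(seq=revcomp(q.seq), circular=True)
            rep = benchmark_genomes(genome, q)
            assert rep.error_summary.counts == base.error_summary.counts
            assert rep.p_distance == base.p_distance

    def test_substitution_count_equals_mismatch_columns(self, genome, manifest):
        prof = ErrorProfile(simple_substitution=7, single_deletion=2, seed=3)
        mut, _ = inject_errors(genome, prof, manifest)
        from mitobench.circular_align import normalize_orientation

        qn = normalize_orientation(genome, mut)
        aln = global_align(genome.seq, qn.seq)
        mismatch_cols = sum(
            r != "-" and q != "-" and r != q
            for r, q in zip(aln.aligned_ref, aln.aligned_qry)
        )
        rep = benchmark_genomes(genome, mut)
        assert rep.error_summary.counts["simple_substitution"] == mismatch_cols == 7

    def test_file_level_benchmark(self, genome, tmp_path):
        ref = tmp_path / "ref.fasta"
        qry = tmp_path / "qry.fasta"
        write_fasta(genome.seq, ref)
        write_fasta(rotate(genome, 100).seq, qry)
        reports = benchmark(ref, qry)
        assert len(reports) == 1 and reports[0].p_distance == 0.0

    def test_no_mitochondrial_length_contig_errors(self, genome, tmp_path):
        ref = tmp_path / "ref.fasta"
        qry = tmp_path / "qry.fasta"
        write_fasta(genome.seq, ref)
        write_fasta(NucSequence(id="tiny", bases="ACGT" * 20), qry)
        with pytest.raises(ValueError):
            benchmark(ref, qry)
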