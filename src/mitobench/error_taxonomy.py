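"""Classification of assembly discrepancies into an error taxonomy.

Long-read (nanopore) assemblies are benchmarked against a gold-standard
short-read assembly by global alignment; every discrepancy is then classified
into one of seven categories:

* ``homopolymer_insertion`` / ``homopolymer_deletion`` — an indel whose
  bases are all one nucleotide X and which is adjacent, on either flank of
  the reference, to a run of X at least ``min_run`` (default 2) bases long.
  These carry a multiplicity label (single, double, ... septuple, gt7) for
  the number of bases added or removed.
* ``simple_substitution`` — a mismatched column (contiguous mismatch runs
  are reported as multiple size-1 substitutions).
* ``single_insertion`` / ``single_deletion`` — a 1-bp indel outside
  homopolymer context.
* ``short_insertion`` / ``short_deletion`` — a >=2-bp indel outside
  homopolymer context.  An insertion whose bases duplicate the adjacent
  reference substring of the same length is additionally flagged
  ``tandem_duplication`` (the flag is advisory; the event still counts once).

Classification operates on left-normalized alignments (``global_align``
guarantees this), so homopolymer and repeat indels have deterministic
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from .circular_align import (
    AccuracyReport,
    AlignmentResult,
    AnchorNotFoundError,
    completeness,
    global_align,
    normalize_orientation,
    p_distance,
)
from .seq_core import CircularGenome, NucSequence, read_fasta, rotate

__all__ = [
    "ErrorEvent",
    "ErrorSummary",
    "CATEGORIES",
    "extract_events",
    "classify_event",
    "summarize",
    "benchmark",
    "benchmark_genomes",
]

CATEGORIES = (
    "homopolymer_insertion",
    "homopolymer_deletion",
    "simple_substitution",
    "single_insertion",
    "short_insertion",
    "single_deletion",
    "short_deletion",
)

MULTIPLICITY_LABELS = {
    1: "single",
    2: "double",
    3: "triple",
    4: "quadruple",
    5: "quintuple",
    6: "sextuple",
    7: "septuple",
}


def multiplicity_label(size: int) -> str:
    return MULTIPLICITY_LABELS.get(size, "gt7")


@dataclass(frozen=True)
class ErrorEvent:
    """One classified discrepancy between query and reference.

    ``ref_pos`` is 1-based: for substitutions and deletions it is the first
    affected reference base; for insertions it is the reference base before
    which the query bases sit.
    """

    category: str
    size: int
    ref_pos: int
    ref_bases: str
    qry_bases: str
    multiplicity_label: Optional[str] = None
    homopolymer_base: Optional[str] = None
    tandem_duplication: bool = False

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("event size must be >= 1")
        if self.category.startswith("homopolymer"):
            if self.multiplicity_label is None or self.homopolymer_base is None:
                raise ValueError(
                    "homopolymer events need multiplicity_label and "
                    "homopolymer_base"
                )
        if "insertion" in self.category and self.ref_bases:
            raise ValueError("insertion events must have empty ref_bases")
        if "deletion" in self.category and self.qry_bases:
            raise ValueError("deletion events must have empty qry_bases")
        if self.category == "simple_substitution" and (
            len(self.ref_bases) != len(self.qry_bases)
        ):
            raise ValueError("substitutions need equal-length ref/qry segments")


@dataclass
class ErrorSummary:
    """Per-category (and per-multiplicity) error tally."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )
    multiplicities: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "homopolymer_insertion": {},
            "homopolymer_deletion": {},
        }
    )

    @property
    def total_errors(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "multiplicities": {k: dict(v) for k, v in self.multiplicities.items()},
            "total_errors": self.total_errors,
        }


def extract_events(aln: AlignmentResult) -> list[ErrorEvent]:
    """Pre-classification events from an alignment.

    Each maximal run of single-sided gap columns becomes one indel event;
    each mismatched column becomes one size-1 substitution.  Indel events
    get placeholder categories (``single/short_insertion/deletion`` by size)
    that ``classify_event`` refines using sequence context.
    """
    events: list[ErrorEvent] = []
    for op in aln.ops():
        if op.kind == "match":
            continue
        if op.kind == "mismatch":
            events.append(
                ErrorEvent(
                    category="simple_substitution",
                    size=1,
                    ref_pos=op.ref_start + 1,
                    ref_bases=op.ref_bases,
                    qry_bases=op.qry_bases,
                )
            )
        elif op.kind == "insertion":
            size = len(op.qry_bases)
            events.append(
                ErrorEvent(
                    category="single_insertion" if size == 1 else "short_insertion",
                    size=size,
                    ref_pos=op.ref_start + 1,
                    ref_bases="",
                    qry_bases=op.qry_bases,
                )
            )
        else:
            size = len(op.ref_bases)
            events.append(
                ErrorEvent(
                    category="single_deletion" if size == 1 else "short_deletion",
                    size=size,
                    ref_pos=op.ref_start + 1,
                    ref_bases=op.ref_bases,
                    qry_bases="",
                )
            )
    return events


def _run_length(s: str, start: int, base: str, step: int) -> int:
    """Length of the run of ``base`` in ``s`` walking from ``start`` by
    ``step`` (+1 right, -1 left)."""
    n = 0
    i = start
    while 0 <= i < len(s) and s[i] == base:
        n += 1
        i += step
    return n


def classify_event(
    e: ErrorEvent, ref: NucSequence, qry: NucSequence, min_run: int = 2
) -> ErrorEvent:
    """Refine an indel's category using reference sequence context.

    An indel is a homopolymer event iff its bases are all one nucleotide X
    and either reference flank carries a run of X of length >= ``min_run``.
    Mixed-base indels never classify as homopolymer events.  Insertions that
    duplicate the adjacent same-length reference substring (either flank,
    because left-normalization moves a duplicated motif's gap to the
    leftmost placement) are flagged ``tandem_duplication``.
    """
    if e.category == "simple_substitution":
        if not (1 <= e.ref_pos <= len(ref)):
            raise ValueError(f"event position {e.ref_pos} outside reference")
        return e

    is_insertion = "insertion" in e.category
    bases = e.qry_bases if is_insertion else e.ref_bases
    size = len(bases)
    rb = ref.bases

    if is_insertion:
        p0 = e.ref_pos - 1  # 0-based insertion point
        if not (0 <= p0 <= len(rb)):
            raise ValueError(f"event position {e.ref_pos} outside reference")
        left_end, right_start = p0 - 1, p0
    else:
        p0 = e.ref_pos - 1
        if not (0 <= p0 and p0 + size <= len(rb)):
            raise ValueError(f"event position {e.ref_pos} outside reference")
        left_end, right_start = p0 - 1, p0 + size

    base = bases[0]
    uniform = bases == base * size
    if uniform:
        left_run = _run_length(rb, left_end, base, -1)
        right_run = _run_length(rb, right_start, base, +1)
        if max(left_run, right_run) >= min_run:
            return replace(
                e,
                category=(
                    "homopolymer_insertion" if is_insertion else "homopolymer_deletion"
                ),
                multiplicity_label=multiplicity_label(size),
                homopolymer_base=base,
            )

    category = (
        ("single_insertion" if size == 1 else "short_insertion")
        if is_insertion
        else ("single_deletion" if size == 1 else "short_deletion")
    )
    tandem = False
    if is_insertion:
        preceding = rb[max(p0 - size, 0) : p0] if p0 - size >= 0 else ""
        following = rb[p0 : p0 + size]
        tandem = bases in (preceding, following) and bool(bases)
    return replace(e, category=category, tandem_duplication=tandem)


def summarize(events: Sequence[ErrorEvent]) -> ErrorSummary:
    """Per-category and per-multiplicity tallies; total equals event count."""
    summary = ErrorSummary()
    for e in events:
        if e.category not in summary.counts:
            raise ValueError(f"unclassified or unknown category {e.category!r}")
        summary.counts[e.category] += 1
        if e.category in summary.multiplicities:
            m = summary.multiplicities[e.category]
            m[e.multiplicity_label] = m.get(e.multiplicity_label, 0) + 1
    return summary


def _events_near_seam(
    events: Sequence[ErrorEvent], genome_len: int, slack: int
) -> bool:
    return any(
        e.ref_pos <= slack or e.ref_pos + e.size - 1 > genome_len - slack
        for e in events
    )


def _benchmark_one(
    ref: CircularGenome,
    qry: CircularGenome,
    min_run: int,
    anchor_k: int,
    scoring: Optional[dict],
    method: str,
) -> tuple[AlignmentResult, list[ErrorEvent]]:
    try:
        qn = normalize_orientation(ref, qry, k=anchor_k)
    except AnchorNotFoundError:
        qn = qry
    aln = global_align(ref.seq, qn.seq, scoring=scoring, method=method)
    raw = extract_events(aln)
    if not qry.circular:
        # terminal indels of a linear (partial) assembly are missing
        # sequence, not assembly errors
        raw = _drop_terminal_indels(raw, aln)
    events = [classify_event(e, ref.seq, qn.seq, min_run=min_run) for e in raw]
    return aln, events


def _drop_terminal_indels(
    events: list[ErrorEvent], aln: AlignmentResult
) -> list[ErrorEvent]:
    # events mirror aln.ops() in order, so terminal indels are the ends
    ops = [o for o in aln.ops() if o.kind != "match"]
    out = list(events)
    if out and ops and ops[0].kind in ("insertion", "deletion"):
        out = out[1:]
    if out and ops and ops[-1].kind in ("insertion", "deletion"):
        out = out[:-1]
    return out


def benchmark_genomes(
    ref: CircularGenome,
    qry: CircularGenome,
    mean_coverage: Optional[float] = None,
    min_run: int = 2,
    anchor_k: int = 21,
    junction_slack: int = 100,
    scoring: Optional[dict] = None,
    method: str = "auto",
) -> AccuracyReport:
    """Full accuracy benchmark of one query genome against a reference.

    Orientation-normalizes the query, aligns end to end, classifies every
    discrepancy and computes p-distance and completeness.  When both
    sequences are circular and any event falls within ``junction_slack``
    bases of the linearization seam, the comparison is repeated with both
    genomes rotated by half their length and the better-scoring event set is
    kept (with coordinates mapped back to the original frame), avoiding
    spurious end gaps at the circular seam.
    """
    aln, events = _benchmark_one(ref, qry, min_run, anchor_k, scoring, method)

    if (
        ref.circular
        and qry.circular
        and junction_slack > 0
        and _events_near_seam(events, len(ref), junction_slack)
    ):
        shift = len(ref) // 2
        ref2 = rotate(ref, shift)
        aln2, events2 = _benchmark_one(
            ref2, qry, min_run, anchor_k, scoring, method
        )
        if aln2.score > aln.score:
            n = len(ref)
            events = [
                replace(e, ref_pos=((e.ref_pos - 1 + shift) % n) + 1)
                for e in events2
            ]
            aln = aln2
            ref = ref2  # metrics below only use lengths / alignment columns

    summary = summarize(events)
    return AccuracyReport(
        n_contigs=1,
        total_length=len(qry),
        mean_coverage=mean_coverage,
        p_distance=p_distance(aln),
        completeness=completeness(ref.seq, qry.seq, aln),
        circular=qry.circular,
        error_summary=summary,
        events=sorted(events, key=lambda e: e.ref_pos),
        query_id=qry.seq.id,
    )


def benchmark(
    ref_fasta: Union[str, Path],
    qry_fasta: Union[str, Path],
    circular: bool = True,
    mean_coverage: Optional[float] = None,
    min_contig_len: int = 1000,
    **kwargs,
) -> list[AccuracyReport]:
    """File-level benchmark: one AccuracyReport per mitochondrial-length
    query contig (contigs shorter than ``min_contig_len`` are ignored;
    if none remain this is an error)."""
    ref_records = read_fasta(ref_fasta)
    if len(ref_records) != 1:
        raise ValueError("reference FASTA must contain exactly one contig")
    ref = CircularGenome(seq=ref_records[0], circular=True)
    contigs = [s for s in read_fasta(qry_fasta) if len(s) >= min_contig_len]
    if not contigs:
        raise ValueError(
            f"no query contig reaches the minimum length {min_contig_len}"
        )
    return [
        benchmark_genomes(
            ref,
            CircularGenome(seq=c, circular=circular),
            mean_coverage=mean_coverage,
            **kwargs,
        )
        for c in contigs
    ]


# ---------------------------------------------------------------------------
# Report writers

_REPORT_COLUMNS = (
    "query_id",
    "n_contigs",
    "circular",
    "total_length",
    "mean_coverage",
    "p_distance",
    "completeness",
    "total_errors",
)

_EVENT_COLUMNS = (
    "ref_pos",
    "category",
    "multiplicity",
    "size",
    "ref_bases",
    "qry_bases",
    "homopolymer_base",
    "tandem_duplication",
)


def report_to_row(r: AccuracyReport) -> dict:
    return {
        "query_id": r.query_id,
        "n_contigs": r.n_contigs,
        "circular": "Circular" if r.circular else "Partial",
        "total_length": r.total_length,
        "mean_coverage": "" if r.mean_coverage is None else r.mean_coverage,
        "p_distance": f"{r.p_distance:.6f}",
        "completeness": f"{r.completeness:.4f}",
        "total_errors": r.error_summary.total_errors,
    }


def write_report_tsv(reports: Sequence[AccuracyReport], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in reports:
            row = report_to_row(r)
            out.write("\t".join(str(row[c]) for c in _REPORT_COLUMNS) + "\n")


def write_report_json(reports: Sequence[AccuracyReport], path: Union[str, Path]) -> None:
    payload = []
    for r in reports:
        row = report_to_row(r)
        row["p_distance"] = r.p_distance
        row["completeness"] = r.completeness
        row["error_summary"] = r.error_summary.to_dict()
        payload.append(row)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_events_tsv(events: Sequence[ErrorEvent], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_EVENT_COLUMNS) + "\n")
        for e in events:
            out.write(
                "\t".join(
                    str(x)
                    for x in (
                        e.ref_pos,
                        e.category,
                        e.multiplicity_label or "",
                        e.size,
                        e.ref_bases,
                        e.qry_bases,
                        e.homopolymer_base or "",
                        e.tandem_duplication,
                    )
                )
                + "\n"
            )
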