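"""Circular-aware pairwise global alignment and accuracy metrics.

Assemblers report a circular chromosome with an arbitrary origin and strand,
so a query assembly must be rotated and possibly reverse-complemented onto
the reference frame before any column-wise comparison is meaningful.  This
module provides:

* ``normalize_orientation`` — anchor the query to the reference start by
  exact k-mer match (forward and reverse strand), rotating circular queries;
* ``global_align`` — end-to-end pairwise global alignment under affine gap
  penalties, with all indels left-normalized (VCF-style) so that event
  coordinates are deterministic;
* ``p_distance`` — proportion of differing sites among comparable (both
  non-gap) columns, the pairwise-deletion convention;
* ``completeness`` — fraction of reference positions covered by query bases.

Two alignment engines sit behind ``global_align``: an exact affine-gap
dynamic program (Biopython's PairwiseAligner) used for short sequences, and
a unit-cost global edit-distance alignment (edlib) used for long,
near-identical genome pairs, where the two produce the same event set after
left-normalization but edlib is several orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
from Bio import Align

from .seq_core import CircularGenome, NucSequence, revcomp, rotate

__all__ = [
    "AlignmentResult",
    "AccuracyReport",
    "AlignedOp",
    "normalize_orientation",
    "global_align",
    "p_distance",
    "completeness",
]

GAP = "-"

#: defaults for the affine scoring scheme (a gap of length L costs
#: gap_open + gap_extend * L)
DEFAULT_SCORING = dict(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)

#: above this length the unit-cost engine is used unless a method is forced
AFFINE_MAX_LEN = 3000


@dataclass(frozen=True)
class AlignedOp:
    """One aligned segment: a run of matches, one mismatch column, or one
    contiguous indel.

    ``ref_start``/``qry_start`` are 0-based positions of the segment in the
    ungapped sequences; for an insertion ``ref_bases`` is empty and
    ``ref_start`` is the position *before which* the query bases sit.
    """

    kind: str  # "match" | "mismatch" | "insertion" | "deletion"
    ref_start: int
    qry_start: int
    ref_bases: str
    qry_bases: str


@dataclass
class AlignmentResult:
    """Column-wise global alignment of a query against a reference."""

    aligned_ref: str
    aligned_qry: str
    ref_start_rotation: int = 0
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_qry):
            raise ValueError("gapped strings must have equal length")
        for a, b in zip(self.aligned_ref, self.aligned_qry):
            if a == GAP and b == GAP:
                raise ValueError("alignment contains a gap-in-both column")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def qry(self) -> str:
        return self.aligned_qry.replace(GAP, "")

    def ops(self) -> list[AlignedOp]:
        """Decompose the alignment into match runs, single mismatch columns
        and contiguous single-sided indel runs."""
        ops: list[AlignedOp] = []
        i = j = c = 0
        n = len(self.aligned_ref)
        ar, aq = self.aligned_ref, self.aligned_qry
        while c < n:
            if ar[c] != GAP and aq[c] != GAP:
                if ar[c] == aq[c]:
                    start = c
                    while c < n and ar[c] != GAP and aq[c] != GAP and ar[c] == aq[c]:
                        c += 1
                    length = c - start
                    ops.append(
                        AlignedOp("match", i, j, ar[start:c], aq[start:c])
                    )
                    i += length
                    j += length
                else:
                    ops.append(AlignedOp("mismatch", i, j, ar[c], aq[c]))
                    i += 1
                    j += 1
                    c += 1
            elif ar[c] == GAP:
                start = c
                while c < n and ar[c] == GAP:
                    c += 1
                ops.append(AlignedOp("insertion", i, j, "", aq[start:c]))
                j += c - start
            else:
                start = c
                while c < n and aq[c] == GAP:
                    c += 1
                ops.append(AlignedOp("deletion", i, j, ar[start:c], ""))
                i += c - start
        return ops


@dataclass
class AccuracyReport:
    """One row of a benchmark report: assembly-level accuracy metrics.

    ``mean_coverage`` is pass-through metadata supplied by the caller (it is
    a property of the read set, not of the sequence comparison).
    """

    n_contigs: int
    total_length: int
    mean_coverage: Optional[float]
    p_distance: float
    completeness: float
    circular: bool
    error_summary: "object" = None  # ErrorSummary; typed loosely to avoid a cycle
    events: list = field(default_factory=list)
    query_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_distance <= 1.0):
            raise ValueError("p_distance must lie in [0, 1]")
        if self.total_length > 0 and not (0.0 < self.completeness <= 1.0 + 1e-12):
            raise ValueError("completeness must lie in (0, 1]")


class AnchorNotFoundError(ValueError):
    """No exact k-mer anchor could orient the query; callers may fall back
    to aligning all rotations explicitly."""


def normalize_orientation(
    ref: CircularGenome, qry: CircularGenome, k: int = 21
) -> CircularGenome:
    """Rotate/flip ``qry`` so it starts at the position matching ``ref``'s
    start.

    The reference's first k-mer is searched exactly in the query (doubled,
    if circular, to cross the seam) and in its reverse complement; on
    failure k is reduced by 2 down to 11 before raising
    ``AnchorNotFoundError``.  Non-circular queries are strand-corrected but
    never rotated.
    """
    if len(ref) == 0 or len(qry) == 0:
        raise ValueError("sequences must be non-empty")
    if k >= min(len(ref), len(qry)):
        raise ValueError("anchor length k must be shorter than both sequences")

    for kk in range(k, 10, -2):
        anchor = ref.bases[:kk]
        for candidate, strand in ((qry, "+"), (_flip(qry), "-")):
            hay = candidate.bases * 2 if candidate.circular else candidate.bases
            pos = hay.find(anchor)
            if pos != -1 and pos < len(candidate):
                if candidate.circular:
                    return rotate(candidate, pos)
                return candidate
    raise AnchorNotFoundError(
        f"no exact anchor of length >= 11 shared between {ref.seq.id!r} and "
        f"{qry.seq.id!r}; consider a full-alignment fallback"
    )


def _flip(g: CircularGenome) -> CircularGenome:
    return CircularGenome(seq=revcomp(g.seq), circular=g.circular)


def _affine_score(ar: str, aq: str, scoring: dict) -> float:
    score = 0.0
    in_gap = False
    for a, b in zip(ar, aq):
        if a == GAP or b == GAP:
            if not in_gap:
                score += scoring["gap_open"]
                in_gap = True
            score += scoring["gap_extend"]
        else:
            in_gap = False
            score += scoring["match"] if a == b else scoring["mismatch"]
    return score


def _align_affine(ref: str, qry: str, scoring: dict) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    # PairwiseAligner's open score already includes the first extension
    aligner.open_gap_score = scoring["gap_open"] + scoring["gap_extend"]
    aligner.extend_gap_score = scoring["gap_extend"]
    aln = aligner.align(ref, qry)[0]
    return str(aln[0]), str(aln[1])


def _align_edit(ref: str, qry: str) -> tuple[str, str]:
    res = edlib.align(qry, ref, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, qry, ref)
    return nice["target_aligned"], nice["query_aligned"]


#: variants closer than this (bp on the reference) are refined together
REFINE_WINDOW = 30
#: matched context kept on each side of a refined cluster
REFINE_PAD = 12


def _refine_ops(
    ops: list[AlignedOp], ref: str, qry: str, scoring: dict
) -> list[AlignedOp]:
    """Locally re-align each cluster of discrepancies under affine scoring.

    A unit-cost global aligner may split one indel into several equal-cost
    gap runs (no gap-open penalty), e.g. inside tandem duplications.  Each
    cluster of variants separated by less than ``REFINE_WINDOW`` matched
    bases is therefore re-aligned with the exact affine-gap DP on a small
    padded window, which strictly prefers contiguous gaps.  Window ends sit
    in matched context, so end-anchoring the local alignment is valid.
    """
    variants = [o for o in ops if o.kind != "match"]
    if not variants:
        return ops

    clusters: list[list[AlignedOp]] = [[variants[0]]]
    for v in variants[1:]:
        prev = clusters[-1][-1]
        if v.ref_start - (prev.ref_start + len(prev.ref_bases)) <= REFINE_WINDOW:
            clusters[-1].append(v)
        else:
            clusters.append([v])

    new_variants: list[AlignedOp] = []
    prev_window_end = 0
    for cluster in clusters:
        first, last = cluster[0], cluster[-1]
        rs = max(first.ref_start - REFINE_PAD, prev_window_end, 0)
        qs = first.qry_start - (first.ref_start - rs)
        re_ = min(last.ref_start + len(last.ref_bases) + REFINE_PAD, len(ref))
        qe = last.qry_start + len(last.qry_bases) + (
            re_ - (last.ref_start + len(last.ref_bases))
        )
        prev_window_end = re_
        if qs < 0 or qe > len(qry) or rs >= re_ or qs >= qe:
            new_variants.extend(cluster)  # degenerate window; keep as-is
            continue
        lr, lq = _align_affine(ref[rs:re_], qry[qs:qe], scoring)
        local = AlignmentResult(aligned_ref=lr, aligned_qry=lq)
        for op in local.ops():
            if op.kind == "match":
                continue
            new_variants.append(
                AlignedOp(
                    op.kind,
                    op.ref_start + rs,
                    op.qry_start + qs,
                    op.ref_bases,
                    op.qry_bases,
                )
            )
    return _merge_ops(new_variants, ref, qry)


def _left_normalize_ops(ops: list[AlignedOp], ref: str, qry: str) -> list[AlignedOp]:
    """Shift every indel to its leftmost equivalent placement.

    An indel may slide left one base at a time while the base entering from
    the left equals the base leaving on the right (the VCF normalization
    rule); sliding never crosses the previous mismatch or indel event, which
    keeps the alignment's column count and score unchanged.
    """
    out: list[AlignedOp] = []
    prev_bound_ref = 0  # first ref position an indel may slide into
    for op in ops:
        if op.kind == "insertion":
            p, s = op.ref_start, op.qry_bases
            q = op.qry_start
            while p > prev_bound_ref and ref[p - 1] == s[-1]:
                p -= 1
                q -= 1
                s = ref[p] + s[:-1]
            op = AlignedOp("insertion", p, q, "", s)
            out.append(op)
            prev_bound_ref = p
        elif op.kind == "deletion":
            p, d = op.ref_start, op.ref_bases
            q = op.qry_start
            while p > prev_bound_ref and ref[p - 1] == d[-1]:
                p -= 1
                q -= 1
                d = ref[p] + d[:-1]
            op = AlignedOp("deletion", p, q, d, "")
            out.append(op)
            prev_bound_ref = p + len(d)
        else:
            out.append(op)
            if op.kind == "mismatch":
                prev_bound_ref = op.ref_start + 1
            # match runs do not bound sliding; indels may slide through them
    return _merge_ops(out, ref, qry)


def _merge_ops(ops: list[AlignedOp], ref: str, qry: str) -> list[AlignedOp]:
    """Rebuild a consistent op list after sliding: regenerate match runs
    between the (now possibly moved) variant ops."""
    variants = [o for o in ops if o.kind in ("mismatch", "insertion", "deletion")]
    variants.sort(key=lambda o: (o.ref_start, o.qry_start))
    out: list[AlignedOp] = []
    i = j = 0
    for v in variants:
        if v.ref_start > i:
            length = v.ref_start - i
            out.append(AlignedOp("match", i, j, ref[i : i + length], qry[j : j + length]))
            i += length
            j += length
        out.append(v)
        i += len(v.ref_bases)
        j += len(v.qry_bases)
    if i < len(ref):
        out.append(AlignedOp("match", i, j, ref[i:], qry[j:]))
    return out


def _gapped_from_ops(ops: list[AlignedOp]) -> tuple[str, str]:
    ar: list[str] = []
    aq: list[str] = []
    for op in ops:
        if op.kind == "insertion":
            ar.append(GAP * len(op.qry_bases))
            aq.append(op.qry_bases)
        elif op.kind == "deletion":
            ar.append(op.ref_bases)
            aq.append(GAP * len(op.ref_bases))
        else:
            ar.append(op.ref_bases)
            aq.append(op.qry_bases)
    return "".join(ar), "".join(aq)


def global_align(
    ref: NucSequence,
    qry: NucSequence,
    scoring: Optional[dict] = None,
    method: str = "auto",
) -> AlignmentResult:
    """End-to-end global alignment of ``qry`` against ``ref``.

    ``method`` is "affine" (exact affine-gap DP), "edit" (unit-cost edit
    distance; appropriate for long, near-identical sequences) or "auto"
    (affine up to ``AFFINE_MAX_LEN``, edit beyond).  The returned alignment
    is left-normalized: every indel sits at its leftmost equivalent
    placement, so homopolymer/repeat indels have deterministic coordinates.
    The reported score is the affine score of the returned alignment path.
    """
    if len(ref) == 0 or len(qry) == 0:
        raise ValueError("cannot align empty sequences")
    scoring = {**DEFAULT_SCORING, **(scoring or {})}
    if method == "auto":
        method = "affine" if max(len(ref), len(qry)) <= AFFINE_MAX_LEN else "edit"
    if method == "affine":
        ar, aq = _align_affine(ref.bases, qry.bases, scoring)
    elif method == "edit":
        ar, aq = _align_edit(ref.bases, qry.bases)
    else:
        raise ValueError(f"unknown alignment method {method!r}")

    raw = AlignmentResult(aligned_ref=ar, aligned_qry=aq)
    ops = raw.ops()
    if method == "edit":
        ops = _refine_ops(ops, ref.bases, qry.bases, scoring)
    ops = _left_normalize_ops(ops, ref.bases, qry.bases)
    ar, aq = _gapped_from_ops(ops)
    result = AlignmentResult(
        aligned_ref=ar,
        aligned_qry=aq,
        score=_affine_score(ar, aq, scoring),
    )
    if result.ref != ref.bases or result.qry != qry.bases:
        raise AssertionError("alignment post-processing corrupted the sequences")
    return result


def p_distance(aln: AlignmentResult) -> float:
    """Proportion of differing sites among columns where both sequences have
    a base (pairwise deletion: gap columns are excluded entirely)."""
    comparable = 0
    diff = 0
    for a, b in zip(aln.aligned_ref, aln.aligned_qry):
        if a != GAP and b != GAP:
            comparable += 1
            if a != b:
                diff += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns in alignment")
    return diff / comparable


def completeness(ref: NucSequence, qry: NucSequence, aln: AlignmentResult) -> float:
    """Fraction of reference positions aligned to a query base."""
    covered = sum(
        1
        for a, b in zip(aln.aligned_ref, aln.aligned_qry)
        if a != GAP and b != GAP
    )
    return covered / len(ref)
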