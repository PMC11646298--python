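"""Microsatellite and tandem-repeat detection for control-region sequences.

The mitochondrial control region (CR) of fish typically carries short
dinucleotide microsatellites and longer (~17-23 bp period) tandem repeats
with possibly fractional copy numbers.  Two scanners are provided:

* ``find_microsatellites`` — maximal *perfect* tandem arrays of short motifs
  (1-6 bp), reported with the leftmost primitive motif;
* ``find_tandem_repeats`` — a simplified seed-and-extend tandem-repeat
  finder: a candidate array is seeded by one perfect period-length
  self-match, extended copy by copy while each additional copy mismatches
  the running consensus in at most ``max_mismatch_frac`` of its positions,
  and summarized by a per-column majority consensus with span/period copies
  rounded to one decimal.

The full probabilistic tandem-repeat model of dedicated finders is not
reimplemented; downstream reporting only consumes the consensus length and
copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .seq_core import NucSequence

__all__ = ["RepeatHit", "find_microsatellites", "find_tandem_repeats"]


@dataclass(frozen=True)
class RepeatHit:
    """One repeat array: 1-based start, motif (or consensus), period,
    fractional copy count and total span in bases."""

    start: int
    motif: str
    motif_len: int
    copies: float
    span: int
    consensus: Optional[str] = None

    def __post_init__(self) -> None:
        if self.motif_len != len(self.motif):
            raise ValueError("motif_len must equal len(motif)")
        if abs(self.span - self.copies * self.motif_len) > self.motif_len / 2 + 0.51:
            raise ValueError("span inconsistent with copies * motif_len")


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_microsatellites(
    s: NucSequence,
    min_motif: int = 1,
    max_motif: int = 6,
    min_copies: float = 3,
) -> list[RepeatHit]:
    """Maximal perfect tandem arrays of motif length in [min_motif, max_motif].

    Copies may be fractional (span / motif length).  Only primitive motifs
    are reported, and each array is reported once, at its leftmost start,
    under its shortest period; nested reports of the same array under
    rotated or repeated motifs are suppressed.
    """
    b = s.bases
    n = len(b)
    hits: list[RepeatHit] = []
    claimed: list[tuple[int, int]] = []  # (start, end) spans already reported
    for m in range(max(1, min_motif), max_motif + 1):
        i = 0
        while i + m < n:
            if b[i] != b[i + m]:
                i += 1
                continue
            # maximal stretch of period-m self-matches starting at i
            j = i
            while j + m < n and b[j] == b[j + m]:
                j += 1
            span = (j - i) + m  # matched stretch plus one full period
            copies = span / m
            motif = b[i : i + m]
            start0, end0 = i, i + span
            if (
                copies >= min_copies
                and _is_primitive(motif)
                and not any(
                    start0 >= cs and end0 <= ce for cs, ce in claimed
                )
            ):
                hits.append(
                    RepeatHit(
                        start=i + 1,
                        motif=motif,
                        motif_len=m,
                        copies=round(copies, 1),
                        span=span,
                    )
                )
                claimed.append((start0, end0))
            i = j + 1
    hits.sort(key=lambda h: h.start)
    return hits


def _consensus(frames: list[str]) -> str:
    """Per-column majority across (possibly ragged) period-length frames;
    ties break toward the earliest frame's base."""
    period = len(frames[0])
    cols: list[str] = []
    for c in range(period):
        votes: dict[str, int] = {}
        order: list[str] = []
        for f in frames:
            if c < len(f):
                if f[c] not in votes:
                    order.append(f[c])
                votes[f[c]] = votes.get(f[c], 0) + 1
        cols.append(max(order, key=lambda x: votes[x]))
    return "".join(cols)


def find_tandem_repeats(
    s: NucSequence,
    min_period: int = 7,
    max_period: int = 30,
    min_copies: float = 1.8,
    max_mismatch_frac: float = 0.2,
) -> list[RepeatHit]:
    """Seed-and-extend scan for approximate tandem repeats.

    A seed is one perfect period-p self-match (p consecutive positions with
    ``s[i] == s[i+p]``, i.e. two identical adjacent copies).  The array is
    then extended one position at a time, rightward then leftward, while the
    mismatch fraction of each additional copy against the first copy stays
    within ``max_mismatch_frac``.  Copies are span/period to one decimal;
    the consensus is the per-column majority across copies.
    """
    b = s.bases
    n = len(b)
    if n <= 2 * min_period:
        return []
    hits: list[RepeatHit] = []
    claimed: list[tuple[int, int]] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i + 2 * p <= n:
            if any(i >= cs and i < ce for cs, ce in claimed):
                i += 1
                continue
            # perfect seed: p consecutive self-matches at lag p
            if all(b[i + k] == b[i + k + p] for k in range(p)):
                start, end = _extend(b, i, p, max_mismatch_frac)
                start, end = _trim_to_best_score(b, start, end, i, p, max_mismatch_frac)
                span = end - start
                copies = round(span / p, 1)
                if copies >= min_copies:
                    frames = [b[x : x + p] for x in range(start, end, p)]
                    cons = _consensus(frames)
                    if _is_primitive(cons) and not any(
                        start >= cs and end <= ce for cs, ce in claimed
                    ):
                        hits.append(
                            RepeatHit(
                                start=start + 1,
                                motif=cons,
                                motif_len=p,
                                copies=copies,
                                span=span,
                                consensus=cons,
                            )
                        )
                        claimed.append((start, end))
                i = end
            else:
                i += 1
    hits.sort(key=lambda h: h.start)
    return hits


def _extend(b: str, seed: int, p: int, max_mm: float) -> tuple[int, int]:
    """Grow a seeded array [seed, seed+2p) outward, one copy at a time.

    Each additional copy is compared to the copy one period closer to the
    seed; the mismatch budget is evaluated *per copy* (a copy, or a trailing
    partial copy, is extended position by position only while its own
    mismatch count stays within ``max_mm`` of the positions compared so
    far), so a diverged flank stops the array at the copy boundary instead
    of being absorbed by matches accumulated earlier.
    """
    n = len(b)

    def grow(pos: int, step: int) -> int:
        # pos: next candidate position (step=+1) / position past it (step=-1)
        while True:
            mm = 0
            clean_prefix = 0  # copy positions matched before any mismatch
            advanced = 0
            for k in range(1, p + 1):
                i = pos + advanced if step == 1 else pos - 1 - advanced
                if not (0 <= i < n):
                    break
                if b[i] != b[i - p * step]:
                    mm += 1
                    if mm > max_mm * p:  # copy cannot meet the tolerance
                        break
                elif mm == 0:
                    clean_prefix = k
                advanced += 1
            if advanced == p and mm <= max_mm * p:
                pos += p * step  # whole copy accepted; try the next one
                continue
            # incomplete or over-budget copy: keep only its clean prefix
            return pos + clean_prefix * step

    end = grow(seed + 2 * p, +1)
    start = grow(seed, -1)
    return start, end


def _trim_to_best_score(
    b: str, start: int, end: int, seed: int, p: int, max_mm: float
) -> tuple[int, int]:
    """Trim each extension to its maximal-scoring prefix.

    Positions score +1 on a period-p self-match and -(1/max_mm - 1) on a
    mismatch, so the break-even mismatch fraction equals ``max_mm``;
    trailing bursts of mismatches that squeezed under the per-copy budget
    are cut back to the last high point, as score-maximizing repeat finders
    do.  The perfect seed copy itself is never trimmed.
    """
    penalty = 1.0 / max_mm - 1.0
    best_end = seed + 2 * p
    score = best = 0.0
    for i in range(seed + 2 * p, end):
        score += 1.0 if b[i] == b[i - p] else -penalty
        if score >= best:
            best, best_end = score, i + 1
    best_start = seed
    score = best = 0.0
    for i in range(seed - 1, start - 1, -1):
        score += 1.0 if b[i] == b[i + p] else -penalty
        if score >= best:
            best, best_start = score, i
    return best_start, best_end
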