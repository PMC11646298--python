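"""Long-read quality filtering and depth subsampling.

Reproduces the two read-level stages of a long-read organelle assembly
pipeline: (1) quality/length filtering of ONT reads — retain reads whose
read-level Q-score is at least a threshold (default 6) and whose length lies
in a window (the study design retains 5,000-20,000 bp for full-depth
assembly); and (2) random subsampling of a read set to a target fold
coverage of a genome (default 1 Gb, the conventional teleost nuclear genome
size), by shuffling reads with a seeded RNG and accumulating them until the
cumulative base count reaches ``target_depth * genome_size``.

The read-level Q-score is the Phred score of the *mean per-base error
probability* (the ONT/fastp convention), not the arithmetic mean of the
per-base Phred scores.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ReadRecord",
    "SubsampleSpec",
    "FilterReport",
    "mean_qscore",
    "filter_reads",
    "subsample_to_depth",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} quals for "
                f"{len(self.bases)} bases"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SubsampleSpec:
    """Target for depth subsampling.

    ``target_depth`` is fold coverage of ``genome_size`` bases; the default
    genome size is 1 Gb, the conventional assumption for a teleost nuclear
    genome when subsampling whole-genome read sets.
    """

    target_depth: float
    genome_size: float = 1e9
    seed: int = 42

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")

    @property
    def target_bases(self) -> float:
        return self.target_depth * self.genome_size


@dataclass
class FilterReport:
    """Counts of reads removed by each filtering criterion."""

    n_input: int = 0
    n_kept: int = 0
    removed_quality: int = 0
    removed_short: int = 0
    removed_long: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def mean_qscore(r: ReadRecord) -> float:
    """Read-level Q: Phred of the mean per-base error probability.

    Converts each per-base Phred score q to an error probability
    10**(-q/10), averages, and converts back with -10*log10.  A read of
    uniform quality q therefore scores exactly q.
    """
    if len(r) == 0:
        raise ValueError(f"read {r.id!r} is empty")
    q = np.asarray(r.quals, dtype=float)
    mean_err = np.mean(10.0 ** (-q / 10.0))
    return float(-10.0 * np.log10(mean_err))


def filter_reads(
    reads: Sequence[ReadRecord],
    min_q: Optional[float] = 6.0,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    report: Optional[FilterReport] = None,
) -> list[ReadRecord]:
    """Quality/length filter; retains reads with mean Q >= min_q and
    min_len <= length <= max_len (both ends inclusive).

    Thresholds set to ``None`` are not applied.  Order is preserved and the
    operation is idempotent.  An optional ``report`` accumulates per-criterion
    removal counts.
    """
    if min_len is not None and max_len is not None and min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if report is None:
        report = FilterReport()
    report.n_input += len(reads)
    kept: list[ReadRecord] = []
    for r in reads:
        if min_len is not None and len(r) < min_len:
            report.removed_short += 1
            continue
        if max_len is not None and len(r) > max_len:
            report.removed_long += 1
            continue
        if min_q is not None and mean_qscore(r) < min_q:
            report.removed_quality += 1
            continue
        kept.append(r)
    report.n_kept += len(kept)
    return kept


def subsample_to_depth(
    reads: Sequence[ReadRecord], spec: SubsampleSpec
) -> list[ReadRecord]:
    """Seeded random subsampling to a target fold coverage.

    Reads are shuffled by a seeded RNG and taken in shuffled order until the
    cumulative base count first reaches ``spec.target_bases`` (the
    shuffle-then-accumulate rule used by coverage-targeted subsamplers).
    The same seed always yields the same selection.  If the whole input does
    not reach the target, all reads are returned with a warning.
    """
    if not reads:
        raise ValueError("cannot subsample an empty read set")
    total = sum(len(r) for r in reads)
    target = spec.target_bases
    if total < target:
        warnings.warn(
            f"input has {total} bases, fewer than the target "
            f"{target:.0f}; returning all reads",
            stacklevel=2,
        )
        return list(reads)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(reads))
    out: list[ReadRecord] = []
    acc = 0
    for i in order:
        out.append(reads[i])
        acc += len(reads[i])
        if acc >= target:
            break
    return out


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, Phred+33), gzip-transparent.


def _open_maybe_gzip(path: Union[str, Path], mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: Union[str, Path]) -> list[ReadRecord]:
    """Read 4-line FASTQ records (Phred+33), transparently gunzipping."""
    reads: list[ReadRecord] = []
    with _open_maybe_gzip(path, "r") as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header: {header!r}")
            bases = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or len(qual) != len(bases):
                raise ValueError(f"malformed FASTQ record {header!r}")
            reads.append(
                ReadRecord(
                    id=header[1:].split()[0],
                    bases=bases.upper(),
                    quals=tuple(ord(c) - 33 for c in qual),
                )
            )
    return reads


def write_fastq(reads: Sequence[ReadRecord], path: Union[str, Path]) -> None:
    """Write reads as 4-line FASTQ (Phred+33); gzip if the path ends in .gz."""
    with _open_maybe_gzip(path, "w") as out:
        for r in reads:
            qual = "".join(chr(min(q, 93) + 33) for q in r.quals)
            out.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def write_summary(report: FilterReport, path: Union[str, Path]) -> None:
    """Write a filter report as JSON or TSV depending on the suffix."""
    path = Path(path)
    d = report.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        keys = list(d)
        path.write_text(
            "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"
        )
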