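"""Sequence data model, FASTA I/O and circular-genome operations.

Mitochondrial genomes are small circular chromosomes (~16.5 kb in teleost
fish) that assemblers report with an arbitrary start coordinate and strand.
This module provides the nucleotide-sequence containers used throughout the
package, rotation and reverse-complement operations for circular sequences,
and whole-sequence nucleotide-usage statistics.

Coordinates are 0-based half-open internally; anything written to a report
is 1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NucSequence",
    "CircularGenome",
    "CompositionTable",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "rotate",
    "nucleotide_usage",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _normalize_bases(raw: str, label: str) -> str:
    """Uppercase, map U->T, and validate against the A/C/G/T/N alphabet."""
    bases = raw.upper().replace("U", "T")
    bad = set(bases) - _ALPHABET
    if bad:
        raise ValueError(
            f"record {label!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return bases


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence over the {A,C,G,T,N} alphabet.

    Bases are normalized at construction (uppercase, U->T); any other
    character raises ``ValueError`` naming the offending record.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "bases", _normalize_bases(self.bases, self.id))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class CircularGenome:
    """A nucleotide sequence plus a circularity flag.

    Circular sequences may be rotated to any origin; ``rotate`` on a
    non-circular genome is an error.
    """

    seq: NucSequence
    circular: bool = True

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def bases(self) -> str:
        return self.seq.bases


@dataclass(frozen=True)
class CompositionTable:
    """Nucleotide usage percentages over the non-N positions of a sequence."""

    a_pct: float
    t_pct: float
    c_pct: float
    g_pct: float
    at_pct: float
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        total = self.a_pct + self.t_pct + self.c_pct + self.g_pct
        if abs(total - 100.0) > 0.02:
            raise ValueError(f"percentages sum to {total}, not 100")
        if abs(self.at_pct - (self.a_pct + self.t_pct)) > 0.02:
            raise ValueError("at_pct must equal a_pct + t_pct")

    @classmethod
    def from_percentages(
        cls, a_pct: float, t_pct: float, c_pct: float, g_pct: float, length: int
    ) -> "CompositionTable":
        """Build a table from per-base percentages, deriving A+T%."""
        return cls(
            a_pct=a_pct,
            t_pct=t_pct,
            c_pct=c_pct,
            g_pct=g_pct,
            at_pct=round(a_pct + t_pct, 2),
            length=length,
        )


def _open_text(path: Union[str, Path]):
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: Union[str, Path]) -> list[NucSequence]:
    """Read all records from a (possibly gzipped) FASTA file.

    Bases are uppercased and U is normalized to T.  An empty file, a record
    with no sequence line, or non-IUPAC characters raise ``ValueError``.
    """
    records: list[NucSequence] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if len(rec.seq) == 0:
                raise ValueError(f"record {rec.id!r} has no sequence")
            records.append(NucSequence(id=rec.id, bases=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    seqs: Union[NucSequence, list[NucSequence]],
    path: Union[str, Path],
    width: int = 70,
) -> None:
    """Write one or more sequences as wrapped FASTA."""
    if isinstance(seqs, NucSequence):
        seqs = [seqs]
    with open(path, "w") as out:
        for s in seqs:
            out.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                out.write(s.bases[i : i + width] + "\n")


def revcomp(s: NucSequence) -> NucSequence:
    """Watson-Crick reverse complement; N maps to N."""
    return NucSequence(id=s.id, bases=s.bases.translate(_COMPLEMENT)[::-1])


def rotate(g: CircularGenome, offset: int) -> CircularGenome:
    """Rotate a circular genome so that position ``offset`` becomes the origin.

    The result's sequence is ``bases[offset:] + bases[:offset]``. Rotating a
    non-circular genome raises ``ValueError``.
    """
    if not g.circular:
        raise ValueError("cannot rotate a non-circular sequence")
    n = len(g)
    offset %= n
    b = g.bases
    return CircularGenome(
        seq=NucSequence(id=g.seq.id, bases=b[offset:] + b[:offset]),
        circular=True,
    )


def nucleotide_usage(s: NucSequence) -> CompositionTable:
    """Percentages of A/T/C/G over the non-N positions of ``s``.

    Percentages are rounded to 2 decimals for reporting, matching the style
    of published mitogenome composition tables; A+T% is the sum of the
    unrounded A and T percentages, rounded once.
    """
    counts = {b: s.bases.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError(f"sequence {s.id!r} contains only N bases")
    a = 100.0 * counts["A"] / denom
    t = 100.0 * counts["T"] / denom
    c = 100.0 * counts["C"] / denom
    g = 100.0 * counts["G"] / denom
    return CompositionTable(
        a_pct=round(a, 2),
        t_pct=round(t, 2),
        c_pct=round(c, 2),
        g_pct=round(g, 2),
        at_pct=round(a + t, 2),
        length=len(s),
    )
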