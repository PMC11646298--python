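"""Codon usage, relative synonymous codon usage (RSCU) and annotation
summaries for mitochondrial genomes.

Codon counting pools all protein-coding genes (PCGs); sequences are expected
strand-correct (negative-strand genes reverse-complemented upstream).  RSCU
for codon i in a synonymous family F is::

    RSCU_i = count_i * |F| / sum_{j in F} count_j

so that the values in each family sum to |F| whenever the family has any
usage at all.  Families are defined by the configured genetic code (default:
vertebrate mitochondrial, NCBI translation table 2); stop codons are
excluded from families by default.  Note that in table 2 AGA and AGG are
terminators, so they fall outside the amino-acid families even though some
published usage tables label them as serine codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio.Data import CodonTable

from .seq_core import NucSequence

__all__ = [
    "CodonUsageTable",
    "GeneAnnotation",
    "count_codons",
    "rscu",
    "annotation_summary",
    "read_annotations",
    "synonymous_families",
]

KINDS = ("PCG", "tRNA", "rRNA", "CR")

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass
class CodonUsageTable:
    """Pooled codon counts over a set of coding sequences."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS}
    )
    code_id: int = 2  # vertebrate mitochondrial

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature with 1-based inclusive coordinates.

    A feature may wrap the circular origin, in which case ``end < start``.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based and positive")

    def length(self, genome_len: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        # wraps the circular origin
        return genome_len - self.start + 1 + self.end


def count_codons(cds_list: Sequence[NucSequence], code_id: int = 2) -> CodonUsageTable:
    """Pooled codon counts across protein-coding sequences.

    A trailing partial codon (sequence length not a multiple of 3) is
    dropped with a warning — mitochondrial PCGs often end in incomplete stop
    codons completed by polyadenylation.
    """
    if not cds_list:
        raise ValueError("no coding sequences given")
    table = CodonUsageTable(code_id=code_id)
    for s in cds_list:
        n3 = len(s) - len(s) % 3
        if n3 < len(s):
            warnings.warn(
                f"{s.id!r}: dropping {len(s) - n3} trailing bases "
                "(partial codon)",
                stacklevel=2,
            )
        for i in range(0, n3, 3):
            codon = s.bases[i : i + 3]
            if codon in table.counts:
                table.counts[codon] += 1
    return table


def synonymous_families(
    code_id: int = 2, include_stop: bool = False
) -> dict[str, list[str]]:
    """Synonymous codon families keyed by amino acid (one-letter code),
    taken from the given NCBI translation table."""
    code = CodonTable.unambiguous_dna_by_id[code_id]
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        if codon in code.stop_codons:
            if include_stop:
                fams.setdefault("*", []).append(codon)
            continue
        aa = code.forward_table[codon]
        fams.setdefault(aa, []).append(codon)
    return fams


def rscu(
    table: CodonUsageTable, include_stop: bool = False
) -> dict[str, float]:
    """Relative synonymous codon usage for every codon in a family.

    Families with zero total usage get RSCU 0 for all members (flagged with
    a warning) rather than NaN.
    """
    values: dict[str, float] = {}
    for aa, fam in synonymous_families(table.code_id, include_stop).items():
        fam_total = sum(table.counts[c] for c in fam)
        if fam_total == 0:
            warnings.warn(f"family {aa!r} has zero usage; RSCU set to 0")
            for c in fam:
                values[c] = 0.0
        else:
            for c in fam:
                values[c] = table.counts[c] * len(fam) / fam_total
    return values


@dataclass
class AnnotationSummary:
    counts_by_kind: dict[str, int]
    counts_by_kind_strand: dict[tuple[str, str], int]
    gene_lengths: dict[str, int]
    cr_flanks: Optional[tuple[str, str]]  # (upstream gene, downstream gene)

    @property
    def total_genes(self) -> int:
        return sum(
            v for (kind, _), v in self.counts_by_kind_strand.items() if kind != "CR"
        )


def annotation_summary(
    anns: Sequence[GeneAnnotation], genome_len: int
) -> AnnotationSummary:
    """Counts by kind and strand, per-gene lengths, and the genes flanking
    the control region (nearest neighbours on the circle)."""
    for a in anns:
        if a.start > genome_len or a.end > genome_len:
            raise ValueError(f"{a.name!r}: coordinates exceed genome length")
    counts_by_kind = {k: 0 for k in KINDS}
    counts_by_ks: dict[tuple[str, str], int] = {}
    lengths: dict[str, int] = {}
    for a in anns:
        counts_by_kind[a.kind] += 1
        key = (a.kind, a.strand)
        counts_by_ks[key] = counts_by_ks.get(key, 0) + 1
        lengths[a.name] = a.length(genome_len)

    cr_flanks = None
    crs = [a for a in anns if a.kind == "CR"]
    genes = sorted((a for a in anns if a.kind != "CR"), key=lambda a: a.start)
    if crs and genes:
        cr = crs[0]

        def circ_gap(up_end: int, down_start: int) -> int:
            return (down_start - up_end) % genome_len

        upstream = min(genes, key=lambda g: circ_gap(g.end, cr.start))
        downstream = min(genes, key=lambda g: circ_gap(cr.end, g.start))
        cr_flanks = (upstream.name, downstream.name)
    return AnnotationSummary(
        counts_by_kind=counts_by_kind,
        counts_by_kind_strand=counts_by_ks,
        gene_lengths=lengths,
        cr_flanks=cr_flanks,
    )


# ---------------------------------------------------------------------------
# Annotation ingestion: GFF3 or a minimal TSV (name, kind, strand, start, end)

_GFF_TYPE_TO_KIND = {
    "CDS": "PCG",
    "gene": "PCG",
    "mRNA": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D_loop": "CR",
    "D-loop": "CR",
    "control_region": "CR",
}


def _gff_attr(attrs: str, *keys: str) -> Optional[str]:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for k in keys:
        if k in fields:
            return fields[k]
    return None


def read_annotations(path: Union[str, Path]) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (1-based inclusive, 9 columns) or a
    minimal tab-separated table with columns name, kind, strand, start, end.

    The format is chosen by inspection: lines with 9 tab-separated columns
    and a numeric 4th/5th column are treated as GFF3.
    """
    path = Path(path)
    anns: list[GeneAnnotation] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) == 9:
            _, _, ftype, start, end, _, strand, _, attrs = cols
            kind = _GFF_TYPE_TO_KIND.get(ftype)
            if kind is None:
                continue
            name = _gff_attr(attrs, "Name", "gene", "product", "ID") or ftype
            anns.append(
                GeneAnnotation(
                    name=name,
                    kind=kind,
                    strand=strand if strand in "+-" else "+",
                    start=int(start),
                    end=int(end),
                )
            )
        elif len(cols) == 5:
            name, kind, strand, start, end = cols
            if name == "name":  # header
                continue
            anns.append(
                GeneAnnotation(
                    name=name, kind=kind, strand=strand,
                    start=int(start), end=int(end),
                )
            )
        else:
            raise ValueError(f"unrecognized annotation line: {line!r}")
    return anns
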