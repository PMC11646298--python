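# Methods

## Scope and model

`mitobench` compares a query assembly of a small circular chromosome (a
fish mitogenome, ~16.5 kb) against a trusted reference assembly and reduces
the comparison to (i) four accuracy metrics — contig count, total length,
coverage, identity — and (ii) a tally of classified error events. It also
reimplements the two read-level stages that precede assembly in a long-read
organelle pipeline (quality/length filtering and depth subsampling) and the
descriptive statistics typically reported for an annotated mitogenome
(composition, codon usage/RSCU, gene counts, control-region repeats).
Assembly itself, annotation, BLAST, polishing and phylogenetics are out of
scope; the benchmark consumes assemblies, it does not produce them.

## Orientation normalization

A circular assembly has no natural origin or strand. Before alignment the
query is anchored: the reference's first k-mer (k = 21, falling back by 2
down to 11) is searched exactly in the query and in its reverse complement,
doubling the query string so the anchor can cross the seam. The query is
reverse-complemented and/or rotated so it begins at the matching position.
If no anchor of length ≥ 11 is shared, an error suggests a full-alignment
fallback rather than silently comparing misoriented sequences. Linear
(partial) queries are strand-corrected but never rotated.

Because the seam could still split an error event sitting at the origin,
the benchmark re-runs the comparison with both genomes rotated by half
their length whenever any event lies within a 100-bp junction slack of
either end, and keeps the better-scoring event set (coordinates are mapped
back to the original frame).

## Global alignment

Alignment is end-to-end (Needleman–Wunsch) under affine gap scoring:
match +2, mismatch −3, gap open −5, gap extend −2, where a gap of length L
costs 5 + 2L. Two engines sit behind one interface:

* an exact affine-gap dynamic program (Biopython's PairwiseAligner) for
  sequences up to 3,000 bp — this is the semantics oracle, checked in the
  tests against an independently written Gotoh recurrence;
* a unit-cost global edit-distance alignment (edlib) for long sequences,
  where the full affine DP on a 16.5-kb pair costs seconds but the
  benchmark needs to run hundreds of comparisons.

A unit-cost aligner has no gap-open penalty, so it may split one indel into
several equal-cost gap runs (this genuinely happens inside tandem
duplications). Every cluster of discrepancies separated by less than 30
matched bases is therefore re-aligned locally with the exact affine DP on a
window padded by 12 matched bases — affine scoring strictly prefers the
contiguous gap, and the window ends sit in matched context so end-anchoring
is valid. Finally, every indel is shifted to its leftmost equivalent
placement (VCF-style normalization; sliding never crosses another event),
which makes homopolymer and repeat indel coordinates deterministic. The
reported score is always the affine score of the returned path.

## Metrics

* **p-distance**: mismatching columns / columns where both sequences have a
  base. Gap columns are excluded entirely (pairwise deletion), so a query
  differing only by indels has p-distance 0.
* **completeness**: fraction of reference positions aligned to a query
  base.
* **total length, contig count, circularity**: taken from the query;
  **coverage** is pass-through metadata supplied by the caller (it is a
  property of the read set, not of the sequence comparison).

For linear queries, indel events touching the alignment termini are not
counted as errors: a truncated assembly is missing sequence, which
completeness already measures.

## Error taxonomy

Events are extracted from the normalized alignment: each maximal run of
single-sided gap columns is one indel event; each mismatched column is one
size-1 simple substitution (there is no multi-base substitution category,
so runs of mismatches count once per column). An indel is a *homopolymer*
insertion/deletion when its bases are all one nucleotide X and either
reference flank of the event carries a run of X at least `min_run` = 2
bases long; sizes 1–7 map to single…septuple, larger events to `gt7`.
Mixed-base indels are never homopolymer events, whatever their
neighbourhood. Non-homopolymer indels are `single_*` (1 bp) or `short_*`
(≥ 2 bp). An insertion equal to the same-length reference substring on
either flank is flagged `tandem_duplication`; the flag is advisory — the
event still counts once, in its size category. (The flank test is two-sided
because left-normalization moves a duplicated motif's gap to the leftmost
placement, where the inserted bases equal the *following* reference
substring.)

Choices the taxonomy leaves open and how they were fixed here: homopolymer
adjacency is tested on the reference strand, on either flank, after
left-normalization; when both flanks qualify, the longer run (then the 5′
one) supplies the context base. A multi-base non-homopolymer gap run counts
as one short event, not several.

## Read pipeline

The read-level Q-score is the Phred value of the mean per-base error
probability, −10·log10(mean(10^(−q/10))) — the convention of ONT tooling
and fastp — not the arithmetic mean of Phred scores; a read of uniform
quality q scores exactly q. Filtering retains reads with Q ≥ 6 and length
inside an inclusive window (5,000–20,000 bp in the study design this
package reproduces). Subsampling shuffles reads with a seeded RNG and
accumulates them until the cumulative base count first reaches
`depth × genome_size` (1 Gb default, the conventional teleost nuclear
genome size), so removing the last selected read drops the total below
target. The same seed always selects the same reads.

## Repeat scanning

*Microsatellites* are maximal perfect tandem arrays with motif length 1–6
and ≥ 3 copies (fractional copies allowed, span/motif length). Only
primitive motifs are reported, leftmost first; nested reports of one array
under longer or rotated motifs are suppressed.

*Tandem repeats* (periods 7–30) use a simplified seed-and-extend scheme in
place of a full probabilistic repeat finder, since downstream reporting
consumes only the consensus length and copy number: a seed is one perfect
period-p self-match (two identical adjacent copies); the array grows copy
by copy while each additional copy mismatches its predecessor in at most
20% of positions, a trailing partial copy must match perfectly, and each
extension is finally trimmed to its maximal-scoring prefix (match +1,
mismatch −4, break-even exactly at the 20% tolerance) so a burst of
mismatches that sneaks under the per-copy budget cannot drag the array into
flanking sequence. The consensus is the per-column majority across copies;
copies are reported as span/period to one decimal. With these defaults a
random 800-bp sequence yields a chance hit in roughly 5% of trials
(expected seed rate ≈ Σ_p n·4^−p ≈ 0.06), which matches the measured
false-positive rate in the tests.

## Codon usage and annotations

Codon counting pools strand-corrected coding sequences, dropping trailing
partial codons with a warning (mitochondrial PCGs often end in incomplete
stop codons completed by polyadenylation). RSCU families come from the
configured genetic code — by default NCBI translation table 2 (vertebrate
mitochondrial), in which AGA/AGG are terminators and therefore excluded
from the amino-acid families even though some published usage tables label
them serine codons. Stop codons are excluded from RSCU by default
(configurable). Families with zero usage report RSCU 0 with a warning
rather than NaN. Annotations are ingested from GFF3 or a minimal
five-column TSV (name, kind, strand, start, end; 1-based inclusive;
features may wrap the origin, handled modularly). The packaged gene-order
fixture is the canonical vertebrate arrangement: 13 PCGs, 22 tRNAs,
2 rRNAs, control region between tRNA-Pro and tRNA-Phe, with nad6 and eight
tRNAs (Q, A, N, C, Y, S2, E, P) on the negative strand.

## Synthetic data: what it emulates, and what it does not

`make_genome` draws an A+T-rich background (default 55% A+T, 16,500 bp,
matching published teleost mitogenomes), plants a configurable set of
homopolymer runs — including an 11-bp T run and a 5-bp A run, the contexts
reported to host nanopore consensus errors — and writes a control-region
segment (831 bp, near the genome end) carrying AT-rich dinucleotide
microsatellites repeated 3–5 times and two tandem repeats (periods 17 and
20 at 5.4 and 4.7 copies by default). Planted arrays get guard bases so
they are maximal, and background bases outside all features are flipped
between the A/T and C/G classes until the genome-wide A+T count matches the
target exactly. The manifest records every feature with 1-based
coordinates.

`inject_errors` mutates a genome with exact per-category counts and returns
the truth event list. Placement rules make exact round-trip recovery a fair
test rather than a lucky one: event footprints (including flanking
homopolymer runs) stay ≥ 10 bp apart, outside the control-region repeat
arrays and ≥ 30 bp from the origin anchor; inserted/deleted segments for
non-homopolymer indels are chosen mixed-base with flanks that forbid
sliding and equal-cost splits, so the optimal alignment provably realizes
each event as a single contiguous discrepancy. Homopolymer events consume
distinct, well-separated runs (longest requirement served first). The
companion `random_error_profile` draws category mixes weighted toward
substitutions and 1-bp indels — the mix reported for low-depth nanopore
assemblies — with geometrically decaying homopolymer multiplicities capped
by the genome's actual run inventory.

`simulate_reads` emulates ONT read sets only at the level the pipeline
consumes: uniform circular start positions with wraparound, a clipped
lognormal length body within 1–20 kb, i.i.d. per-base
substitution/insertion/deletion errors at configurable rates, and Gaussian
per-base Phred scores around a mean. It does not model signal-level or
pore-kinetic error structure, quality/error correlation, or chimeric
reads. Depth is specified directly against the simulated mitogenome; real
whole-genome experiments subsample against the nuclear genome (the 1 Gb
convention, exposed separately in the subsampler), which the simulator does
not reproduce at desk scale. Consequently, passing tests demonstrate the
*benchmarking machinery* — rotation/strand invariance, exact event
recovery, metric arithmetic — not the error profile of any real assembler
or flowcell; headline error counts from real data depend on assembler
behaviour that is explicitly out of scope.

## Numerical and interface conventions

Internal coordinates are 0-based half-open; all reported coordinates are
1-based inclusive. Sequences are normalized on ingestion (uppercase, U→T;
anything outside A/C/G/T/N is an error naming the record). N bases are
excluded from composition denominators. Composition percentages are
rounded to 2 decimals for reporting, with A+T% computed before rounding;
repeat copy numbers to 1 decimal; p-distance printed to 6 decimals.
FASTA/FASTQ readers are gzip-transparent; FASTQ is 4-line Phred+33.
Alignment tie-breaks are fixed by left-normalization (leftmost gap
placement). The subsampler seed defaults to 42 in the library and is
mandatory in the CLI.

## Problem sizes

All benchmarks and tests run on 16.5-kb genomes; the acceptance checks use
100 random genome/profile pairs with 1–60 injected events (~10 s), 20
rotations/reflections of one mutated query (~2 s), 50 substitution-only
pairs for the p-distance oracle, and constructed repeat arrays of 92 and
53 bp. Simulated read sets range from 1× to 60× mitogenome coverage
(~1 Mb of bases at the top end).

## Known limitations

* The unit-cost + local-affine-refinement strategy assumes discrepancies
  are sparse (assemblies near identity). Queries diverging by more than
  ~20% would degrade to one giant refinement window; use the exact affine
  method for such comparisons.
* The tandem-repeat scanner reports one array per claimed span under the
  smallest seeding period; heavily nested repeat structure (repeats within
  repeats) is reported only at the innermost period.
* Homopolymer classification follows the reference strand only; an indel
  adjacent to a run present in the query but not the reference is not a
  homopolymer event.
* The error injector refuses profiles it cannot place unambiguously rather
  than degrading placement guarantees; very dense profiles (hundreds of
  events on 16.5 kb) may be unsatisfiable.
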