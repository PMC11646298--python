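"""Synthetic inputs for the whole pipeline.

Generates, reproducibly from a seed:

* circular, A+T-rich (~55%) mitogenome-like sequences of ~16.5 kb with
  planted homopolymer runs (including a long 11-bp T run and a 5-bp A run,
  the contexts where nanopore assemblies err) and a control-region-like
  segment carrying dinucleotide microsatellites and 17-23-bp tandem repeats;
* error-mutated copies of a genome with *exact* per-category error counts
  plus a truth event list (the round-trip oracle for the error taxonomy);
* ONT-like read sets: 1-20 kb reads starting uniformly on the circle (with
  wraparound), i.i.d. per-base substitution/insertion/deletion errors and
  Phred qualities around a configurable mean;
* the canonical vertebrate mitochondrial gene order (13 PCGs, 22 tRNAs,
  2 rRNAs, control region between tRNA-Pro and tRNA-Phe; 8 tRNAs and nad6 on
  the negative strand), shipped as a small TSV fixture.

Injected errors are placed so that truth classification is unambiguous:
event footprints (including any flanking homopolymer run) are kept >= 10 bp
apart, outside the control-region repeat arrays and away from the first
30 bp of the origin (the anchor used for rotation normalization).  Under
these placement rules the optimal global alignment provably realizes each
event as a single contiguous discrepancy, which is what makes exact
round-trip recovery a fair test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .codon_stats import GeneAnnotation
from .error_taxonomy import ErrorEvent, multiplicity_label
from .read_pipeline import ReadRecord
from .seq_core import CircularGenome, NucSequence

__all__ = [
    "GenomeSpec",
    "CRSpec",
    "ErrorProfile",
    "ReadSimSpec",
    "make_genome",
    "inject_errors",
    "simulate_reads",
    "random_error_profile",
    "gene_order_fixture",
]

ORIGIN_MARGIN = 30  # bp at the origin kept error-free (rotation anchor)
EVENT_GUARD = 10  # bp of separation around each injected event footprint

#: default planted homopolymer runs (base, run length, approximate position):
#: includes the 11-bp T run and 5-bp A run observed to host errors in fish
#: mitogenomes, plus assorted long runs so profiles up to septuple
#: multiplicity have qualifying sites.
DEFAULT_HOMOPOLYMER_RUNS = (
    ("T", 11, 8000),
    ("A", 5, 3000),
    ("A", 9, 1500),
    ("G", 8, 2200),
    ("A", 6, 2600),
    ("T", 8, 4000),
    ("C", 8, 4500),
    ("C", 6, 5200),
    ("G", 9, 6000),
    ("A", 8, 6800),
    ("T", 7, 7000),
    ("C", 7, 7600),
    ("T", 10, 9000),
    ("G", 6, 9500),
    ("G", 7, 10000),
    ("C", 5, 10500),
    ("T", 6, 11000),
    ("A", 10, 11500),
    ("T", 9, 12500),
    ("C", 9, 13000),
    ("A", 7, 13500),
    ("G", 10, 14200),
)


@dataclass(frozen=True)
class CRSpec:
    """Control-region plant list: dinucleotide microsatellites (motif,
    integer copies) and tandem repeats (period, fractional copies)."""

    length: int = 831
    microsatellites: tuple[tuple[str, int], ...] = (
        ("AT", 4), ("TA", 5), ("AT", 3), ("CA", 4),
        ("TA", 4), ("AT", 5), ("TG", 3), ("TA", 3),
    )
    tandem_repeats: tuple[tuple[int, float], ...] = ((17, 5.4), (20, 4.7))


@dataclass(frozen=True)
class GenomeSpec:
    """Specification of a synthetic circular mitogenome."""

    length: int = 16500
    at_fraction: float = 0.55
    homopolymer_runs: tuple[tuple[str, int, int], ...] = DEFAULT_HOMOPOLYMER_RUNS
    cr_spec: Optional[CRSpec] = CRSpec()
    seed: int = 0


@dataclass(frozen=True)
class ErrorProfile:
    """Exact per-category error counts to inject.

    Homopolymer categories are keyed by multiplicity (1..7 bases added or
    removed); ``tandem_duplications`` lists the motif length of each
    duplication event to inject (each is a short/single insertion flagged
    tandem_duplication).
    """

    simple_substitution: int = 0
    single_insertion: int = 0
    short_insertion: int = 0
    single_deletion: int = 0
    short_deletion: int = 0
    homopolymer_insertion: tuple[tuple[int, int], ...] = ()  # (multiplicity, n)
    homopolymer_deletion: tuple[tuple[int, int], ...] = ()
    tandem_duplications: tuple[int, ...] = ()
    seed: int = 0

    @property
    def total(self) -> int:
        return (
            self.simple_substitution
            + self.single_insertion
            + self.short_insertion
            + self.single_deletion
            + self.short_deletion
            + sum(n for _, n in self.homopolymer_insertion)
            + sum(n for _, n in self.homopolymer_deletion)
            + len(self.tandem_duplications)
        )

    def expected_counts(self) -> dict[str, int]:
        """Per-category counts as the benchmark should report them."""
        return {
            "simple_substitution": self.simple_substitution,
            "single_insertion": self.single_insertion,
            "short_insertion": self.short_insertion + len(self.tandem_duplications),
            "single_deletion": self.single_deletion,
            "short_deletion": self.short_deletion,
            "homopolymer_insertion": sum(n for _, n in self.homopolymer_insertion),
            "homopolymer_deletion": sum(n for _, n in self.homopolymer_deletion),
        }


@dataclass(frozen=True)
class ReadSimSpec:
    """ONT-like read simulation parameters.

    ``depth`` is fold coverage of the simulated mitogenome itself (the
    pipeline's nuclear-genome depth convention is a property of real
    whole-genome read sets; at desk scale depth is exposed directly on the
    simulated template).
    """

    depth: float = 30.0
    min_len: int = 1000
    max_len: int = 20000
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    mean_q: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("error rates must lie in [0, 1)")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid read length range")


# ---------------------------------------------------------------------------
# Genome construction


def _random_bases(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    return rng.choice(np.array(list("ATCG")), size=n, p=probs)


def _other_bases(*exclude: str) -> list[str]:
    return [b for b in "ACGT" if b not in exclude]


def make_genome(spec: GenomeSpec) -> tuple[CircularGenome, dict]:
    """Seeded synthetic circular mitogenome plus a feature manifest.

    The manifest records every planted homopolymer run, microsatellite and
    tandem repeat with 1-based coordinates, and the control-region bounds.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    arr = _random_bases(rng, n, spec.at_fraction)
    manifest: dict = {
        "length": n,
        "homopolymer_runs": [],
        "microsatellites": [],
        "tandem_repeats": [],
        "cr": None,
    }
    occupied: list[tuple[int, int]] = [(0, ORIGIN_MARGIN)]

    def reserve(start: int, end: int) -> bool:
        for s, e in occupied:
            if start < e + 5 and end > s - 5:
                return False
        occupied.append((start, end))
        return True

    # control region first (largest feature), placed near the genome end as
    # in vertebrate mitogenomes
    if spec.cr_spec is not None:
        cr = spec.cr_spec
        cr_start = n - cr.length - 150
        if cr_start <= ORIGIN_MARGIN:
            raise ValueError("genome too short for the requested control region")
        _plant_cr(arr, cr, cr_start, rng, manifest)
        occupied.append((cr_start - 2, cr_start + cr.length + 2))
        manifest["cr"] = {"start": cr_start + 1, "end": cr_start + cr.length}

    for base, run_len, pos in spec.homopolymer_runs:
        placed = False
        for attempt in range(50):
            start = int(pos) + (0 if attempt == 0 else int(rng.integers(-200, 200)))
            start = max(ORIGIN_MARGIN + 2, min(start, n - run_len - 2))
            if reserve(start - 1, start + run_len + 1):
                arr[start : start + run_len] = base
                arr[start - 1] = rng.choice(_other_bases(base))
                arr[start + run_len] = rng.choice(_other_bases(base))
                manifest["homopolymer_runs"].append(
                    {"base": base, "length": run_len, "start": start + 1}
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place homopolymer run ({base}, {run_len}) near {pos}"
            )

    _balance_composition(arr, spec.at_fraction, occupied, rng)
    genome = CircularGenome(
        seq=NucSequence(id=f"synthetic_mitogenome_seed{spec.seed}", bases="".join(arr)),
        circular=True,
    )
    at = _at_fraction(genome.bases)
    if abs(at - spec.at_fraction) > 0.01:
        raise ValueError(
            f"realized A+T fraction {at:.3f} misses target {spec.at_fraction:.3f}"
        )
    manifest["at_fraction"] = round(at, 4)
    return genome, manifest


def _balance_composition(
    arr: np.ndarray,
    at_target: float,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Flip background bases (outside planted features) between the A/T and
    C/G classes until the genome-wide A+T count hits the target exactly.

    Planted features are AT-biased (control region, A/T homopolymer runs),
    so the raw draw overshoots the target; compensating in the free
    background keeps every planted feature intact."""
    n = len(arr)
    free = np.ones(n, dtype=bool)
    for s, e in occupied:
        free[max(0, s) : min(n, e)] = False
    is_at = np.isin(arr, list("AT"))
    target = round(at_target * n)
    excess = int(is_at.sum()) - target  # >0: too many A/T
    if excess == 0:
        return
    from_class, to_class = ("AT", "CG") if excess > 0 else ("CG", "AT")
    candidates = np.flatnonzero(free & np.isin(arr, list(from_class)))
    k = min(abs(excess), len(candidates))
    picks = rng.choice(candidates, size=k, replace=False)
    arr[picks] = rng.choice(list(to_class), size=k)


def _at_fraction(bases: str) -> float:
    return (bases.count("A") + bases.count("T")) / len(bases)


def _plant_cr(
    arr: np.ndarray, cr: CRSpec, cr_start: int, rng: np.random.Generator, manifest: dict
) -> None:
    """Write an A+T-rich control-region segment with guarded repeat arrays."""
    # AT-rich background for the CR
    arr[cr_start : cr_start + cr.length] = _random_bases(rng, cr.length, 0.64)
    cursor = cr_start + 10
    for motif, copies in cr.microsatellites:
        array = (motif * copies)
        start = cursor
        guards = _other_bases(*set(motif))
        # two guard bases each side stop the period-2 self-match extending
        arr[start - 2] = guards[0]
        arr[start - 1] = guards[-1]
        arr[start : start + len(array)] = list(array)
        arr[start + len(array)] = guards[0]
        arr[start + len(array) + 1] = guards[-1]
        manifest["microsatellites"].append(
            {"motif": motif, "copies": copies, "start": start + 1}
        )
        cursor = start + len(array) + 2 + int(rng.integers(8, 20))
    for period, copies in cr.tandem_repeats:
        motif = "".join(_random_bases(rng, period, 0.7))
        # a primitive, mixed motif keeps detection unambiguous
        while len(set(motif)) < 3:
            motif = "".join(_random_bases(rng, period, 0.7))
        span = round(period * copies)
        array = (motif * (span // period + 2))[:span]
        start = cursor
        arr[start : start + span] = list(array)
        # guard bases break the periodic self-match at both flanks
        arr[start - 1] = _other_bases(array[period - 1])[int(rng.integers(0, 3))]
        arr[start + span] = _other_bases(array[span - period])[int(rng.integers(0, 3))]
        manifest["tandem_repeats"].append(
            {"motif": motif, "period": period, "copies": copies, "start": start + 1}
        )
        cursor = start + span + 1 + int(rng.integers(8, 20))
    if cursor >= cr_start + cr.length:
        raise ValueError("control-region plant list does not fit in the CR")


# ---------------------------------------------------------------------------
# Error injection


@dataclass
class _Edit:
    """A planned mutation on the reference: replace ref[start:end) with
    ``replacement``."""

    start: int
    end: int
    replacement: str
    truth: ErrorEvent


class _Placer:
    """Tracks blocked intervals so event footprints stay separated."""

    def __init__(self, n: int, blocked: list[tuple[int, int]]):
        self.n = n
        self.blocked = np.zeros(n, dtype=bool)
        for s, e in blocked:
            self.blocked[max(0, s) : min(n, e)] = True

    def free(self, start: int, end: int) -> bool:
        start, end = max(0, start), min(self.n, end)
        return not self.blocked[start:end].any()

    def claim(self, start: int, end: int) -> None:
        self.blocked[max(0, start - EVENT_GUARD) : min(self.n, end + EVENT_GUARD)] = True


def _maximal_runs(b: str, min_len: int = 2) -> list[tuple[int, str, int]]:
    """(start, base, length) of every maximal homopolymer run >= min_len."""
    runs = []
    i = 0
    n = len(b)
    while i < n:
        j = i
        while j < n and b[j] == b[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, b[i], j - i))
        i = j
    return runs


_RUN_SPACING = 45  # start-to-start distance guaranteeing guard zones never collide


def _spaced_runs(
    b: str, manifest: Optional[dict] = None
) -> list[tuple[int, str, int]]:
    """A mutually well-separated subset of homopolymer runs, longest kept
    first, excluding the origin margin and the control-region repeat arrays.

    Both the profile generator and the injector draw homopolymer sites from
    this subset, so a profile whose multiplicities fit the subset's
    inventory is injectable by construction.
    """
    runs = _maximal_runs(b, min_len=2)
    lo = hi = None
    if manifest and manifest.get("cr"):
        lo, hi = manifest["cr"]["start"] - 1, manifest["cr"]["end"]
    kept: list[tuple[int, str, int]] = []
    for run in sorted(runs, key=lambda r: -r[2]):
        start = run[0]
        if start < ORIGIN_MARGIN + 2 or start + run[2] > len(b) - 2:
            continue
        if lo is not None and lo - 5 <= start <= hi + 5:
            continue
        if all(abs(start - k[0]) >= _RUN_SPACING for k in kept):
            kept.append(run)
    kept.sort(key=lambda r: r[0])
    return kept


def inject_errors(
    g: CircularGenome,
    profile: ErrorProfile,
    manifest: Optional[dict] = None,
) -> tuple[CircularGenome, list[ErrorEvent]]:
    """Mutate a genome with exact per-category error counts.

    Returns the mutated genome and the truth event list (classified
    categories, 1-based reference coordinates, sorted by position).  Raises
    ``ValueError`` naming the unmet categories if the genome lacks
    qualifying, non-overlapping sites for the requested profile.
    """
    b = g.bases
    n = len(b)
    rng = np.random.default_rng(profile.seed)

    blocked = [(0, ORIGIN_MARGIN)]
    if manifest:
        for ms in manifest.get("microsatellites", []):
            s = ms["start"] - 1
            blocked.append((s - 3, s + len(ms["motif"]) * ms["copies"] + 3))
        for tr in manifest.get("tandem_repeats", []):
            s = tr["start"] - 1
            blocked.append((s - 3, s + round(tr["period"] * tr["copies"]) + 3))
        if manifest.get("cr"):
            blocked.append((manifest["cr"]["start"] - 1, manifest["cr"]["end"]))
    placer = _Placer(n, blocked)

    edits: list[_Edit] = []
    unmet: list[str] = []

    # --- homopolymer events consume distinct well-separated runs; place
    # them first (longest requirement first, shortest qualifying run taken)
    # so short events never starve long ones of sites
    runs = _spaced_runs(b, manifest)
    used_runs: set[int] = set()

    def take_run(min_len: int) -> Optional[tuple[int, str, int]]:
        candidates = [
            (length, idx)
            for idx, (start, base, length) in enumerate(runs)
            if idx not in used_runs
            and length >= min_len
            and placer.free(runs[idx][0] - 2, runs[idx][0] + length + 2)
        ]
        if not candidates:
            return None
        _, idx = min(candidates)
        start, base, length = runs[idx]
        used_runs.add(idx)
        placer.claim(start - 1, start + length + 1)
        return (start, base, length)

    for mult, count in sorted(profile.homopolymer_deletion, reverse=True):
        for _ in range(count):
            site = take_run(mult + 2)
            if site is None:
                unmet.append(f"homopolymer_deletion x{mult}")
                continue
            start, base, _length = site
            edits.append(
                _Edit(
                    start,
                    start + mult,
                    "",
                    ErrorEvent(
                        category="homopolymer_deletion",
                        size=mult,
                        ref_pos=start + 1,
                        ref_bases=base * mult,
                        qry_bases="",
                        multiplicity_label=multiplicity_label(mult),
                        homopolymer_base=base,
                    ),
                )
            )

    for mult, count in profile.homopolymer_insertion:
        for _ in range(count):
            site = take_run(2)
            if site is None:
                unmet.append(f"homopolymer_insertion x{mult}")
                continue
            start, base, _length = site
            edits.append(
                _Edit(
                    start,
                    start,
                    base * mult,
                    ErrorEvent(
                        category="homopolymer_insertion",
                        size=mult,
                        ref_pos=start + 1,
                        ref_bases="",
                        qry_bases=base * mult,
                        multiplicity_label=multiplicity_label(mult),
                        homopolymer_base=base,
                    ),
                )
            )

    # --- tandem duplications: duplicate the motif ending at p
    for motif_len in profile.tandem_duplications:
        placed = False
        for _ in range(400):
            p = int(rng.integers(ORIGIN_MARGIN + motif_len + 2, n - 2))
            motif = b[p - motif_len : p]
            if (
                len(set(motif)) >= 2
                and b[p - motif_len - 1] != motif[-1]
                and placer.free(p - motif_len - 2, p + 2)
            ):
                placer.claim(p - motif_len, p + 1)
                edits.append(
                    _Edit(
                        p,
                        p,
                        motif,
                        ErrorEvent(
                            category=(
                                "single_insertion" if motif_len == 1 else "short_insertion"
                            ),
                            size=motif_len,
                            # left-normalization slides the gap through the
                            # motif to its start
                            ref_pos=p - motif_len + 1,
                            ref_bases="",
                            qry_bases=motif,
                            tandem_duplication=True,
                        ),
                    )
                )
                placed = True
                break
        if not placed:
            unmet.append(f"tandem_duplication motif {motif_len}")

    # --- generic site draw for the remaining categories
    def draw_site(width: int, cond) -> Optional[int]:
        for _ in range(600):
            p = int(rng.integers(ORIGIN_MARGIN + 2, n - width - 2))
            if placer.free(p - 2, p + width + 2) and cond(p):
                placer.claim(p - 1, p + width + 1)
                return p
        return None

    for _ in range(profile.simple_substitution):
        p = draw_site(1, lambda p: True)
        if p is None:
            unmet.append("simple_substitution")
            continue
        new = str(rng.choice(_other_bases(b[p])))
        edits.append(
            _Edit(
                p,
                p + 1,
                new,
                ErrorEvent(
                    category="simple_substitution",
                    size=1,
                    ref_pos=p + 1,
                    ref_bases=b[p],
                    qry_bases=new,
                ),
            )
        )

    for _ in range(profile.single_insertion):
        p = draw_site(1, lambda p: len(_other_bases(b[p - 1], b[p])) > 0)
        if p is None:
            unmet.append("single_insertion")
            continue
        base = str(rng.choice(_other_bases(b[p - 1], b[p])))
        edits.append(
            _Edit(
                p,
                p,
                base,
                ErrorEvent(
                    category="single_insertion",
                    size=1,
                    ref_pos=p + 1,
                    ref_bases="",
                    qry_bases=base,
                ),
            )
        )

    for _ in range(profile.short_insertion):
        size = int(rng.integers(2, 7))
        p = draw_site(size, lambda p: len(_other_bases(b[p - 1], b[p])) >= 2)
        if p is None:
            unmet.append("short_insertion")
            continue
        x, y = _other_bases(b[p - 1], b[p])[:2]
        ins = ((x + y) * size)[:size]
        edits.append(
            _Edit(
                p,
                p,
                ins,
                ErrorEvent(
                    category="short_insertion",
                    size=size,
                    ref_pos=p + 1,
                    ref_bases="",
                    qry_bases=ins,
                ),
            )
        )

    def deletable_single(p: int) -> bool:
        return b[p - 1] != b[p] and b[p + 1] != b[p]

    for _ in range(profile.single_deletion):
        p = draw_site(1, deletable_single)
        if p is None:
            unmet.append("single_deletion")
            continue
        edits.append(
            _Edit(
                p,
                p + 1,
                "",
                ErrorEvent(
                    category="single_deletion",
                    size=1,
                    ref_pos=p + 1,
                    ref_bases=b[p],
                    qry_bases="",
                ),
            )
        )

    for _ in range(profile.short_deletion):
        size = int(rng.integers(2, 7))

        def deletable_short(p: int, size=size) -> bool:
            seg = b[p : p + size]
            return (
                len(set(seg)) >= 2  # mixed: never homopolymer context
                and b[p - 1] != seg[-1]  # cannot slide left
                and b[p + size] not in seg[1:]  # no equal-cost split
                and b[p + size] != seg[0]  # cannot slide right
            )

        p = draw_site(size, deletable_short)
        if p is None:
            unmet.append("short_deletion")
            continue
        edits.append(
            _Edit(
                p,
                p + size,
                "",
                ErrorEvent(
                    category="short_deletion",
                    size=size,
                    ref_pos=p + 1,
                    ref_bases=b[p : p + size],
                    qry_bases="",
                ),
            )
        )

    if unmet:
        raise ValueError(
            "error profile unsatisfiable on this genome; unmet: " + ", ".join(unmet)
        )

    # apply edits right-to-left so earlier coordinates stay valid
    mutated = b
    for e in sorted(edits, key=lambda e: e.start, reverse=True):
        mutated = mutated[: e.start] + e.replacement + mutated[e.end :]

    truth = sorted((e.truth for e in edits), key=lambda t: t.ref_pos)
    out = CircularGenome(
        seq=NucSequence(id=g.seq.id + "_mut", bases=mutated) if edits else g.seq,
        circular=g.circular,
    )
    return out, truth


def random_error_profile(
    genome: CircularGenome,
    total: int,
    seed: int,
    manifest: Optional[dict] = None,
) -> ErrorProfile:
    """A random, *satisfiable* error profile with the requested total count.

    Category weights favour substitutions and 1-bp indels (the mix reported
    for low-depth nanopore assemblies); homopolymer multiplicities decay
    geometrically and are capped by the genome's inventory of qualifying
    runs, so the profile is injectable by construction.
    """
    rng = np.random.default_rng(seed)
    # same site inventory the injector will use
    run_lengths = sorted(
        (length for _, _, length in _spaced_runs(genome.bases, manifest))
    )

    counts = {
        "simple_substitution": 0,
        "single_insertion": 0,
        "short_insertion": 0,
        "single_deletion": 0,
        "short_deletion": 0,
    }
    hp_ins: dict[int, int] = {}
    hp_del: dict[int, int] = {}
    n_tandem = 0

    def consume_run(min_len: int) -> bool:
        """Remove the shortest run of at least min_len from the inventory."""
        for i, length in enumerate(run_lengths):
            if length >= min_len:
                run_lengths.pop(i)
                return True
        return False

    cats = list(counts) + ["homopolymer_insertion", "homopolymer_deletion", "tandem"]
    weights = np.array([0.30, 0.13, 0.08, 0.13, 0.08, 0.12, 0.12, 0.04])
    weights /= weights.sum()
    for _ in range(total):
        c = str(rng.choice(cats, p=weights))
        if c in ("homopolymer_insertion", "homopolymer_deletion"):
            mult = min(int(rng.geometric(0.55)), 7)
            if c == "homopolymer_deletion":
                while mult >= 1 and not consume_run(mult + 2):
                    mult -= 1
                if mult < 1:
                    counts["simple_substitution"] += 1
                    continue
                hp_del[mult] = hp_del.get(mult, 0) + 1
            else:
                if not consume_run(2):
                    counts["simple_substitution"] += 1
                    continue
                hp_ins[mult] = hp_ins.get(mult, 0) + 1
        elif c == "tandem":
            n_tandem += 1
        else:
            counts[c] += 1

    return ErrorProfile(
        **counts,
        homopolymer_insertion=tuple(sorted(hp_ins.items())),
        homopolymer_deletion=tuple(sorted(hp_del.items())),
        tandem_duplications=tuple(
            int(rng.integers(8, 20)) for _ in range(n_tandem)
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(g: CircularGenome, spec: ReadSimSpec) -> list[ReadRecord]:
    """Simulate ONT-like reads from a circular template.

    Start positions are uniform on the circle (reads wrap the origin);
    lengths follow a clipped lognormal body within [min_len, max_len];
    substitutions/insertions/deletions are drawn i.i.d. per base at the
    stated rates; per-base Phred scores are normal around ``mean_q``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(g)
    doubled = g.bases * 2 if g.circular else g.bases
    target = spec.depth * n
    mu = np.log(np.sqrt(spec.min_len * spec.max_len))
    reads: list[ReadRecord] = []
    acc = 0
    i = 0
    while acc < target:
        length = int(np.clip(rng.lognormal(mu, 0.55), spec.min_len, spec.max_len))
        length = min(length, n)
        start = int(rng.integers(0, n)) if g.circular else int(
            rng.integers(0, max(1, n - length + 1))
        )
        template = doubled[start : start + length]
        bases, quals = _apply_read_errors(template, spec, rng)
        reads.append(ReadRecord(id=f"sim_read_{i}", bases=bases, quals=quals))
        acc += len(bases)
        i += 1
    return reads


_BASE_ARR = np.array(list("ACGT"))


def _apply_read_errors(
    template: str, spec: ReadSimSpec, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    m = len(template)
    if spec.sub_rate == spec.ins_rate == spec.del_rate == 0.0:
        quals = np.rint(
            np.clip(rng.normal(spec.mean_q, 2.0, size=m), 2, 60)
        ).astype(int)
        return template, tuple(int(q) for q in quals)
    arr = np.array(list(template))
    u = rng.random(m)
    # substitutions
    sub_mask = u < spec.sub_rate
    if sub_mask.any():
        offs = rng.integers(1, 4, size=int(sub_mask.sum()))
        idx = np.searchsorted(_BASE_ARR, arr[sub_mask])
        # map base -> index via lookup
        lut = {b: i for i, b in enumerate("ACGT")}
        idx = np.array([lut.get(x, 0) for x in arr[sub_mask]])
        arr[sub_mask] = _BASE_ARR[(idx + offs) % 4]
    # deletions
    del_mask = rng.random(m) < spec.del_rate
    # insertions (after each surviving base)
    ins_mask = rng.random(m) < spec.ins_rate
    out: list[str] = []
    for i in range(m):
        if not del_mask[i]:
            out.append(arr[i])
        if ins_mask[i]:
            out.append(str(_BASE_ARR[int(rng.integers(0, 4))]))
    bases = "".join(out)
    quals = np.rint(
        np.clip(rng.normal(spec.mean_q, 2.0, size=len(bases)), 2, 60)
    ).astype(int)
    return bases, tuple(int(q) for q in quals)


# ---------------------------------------------------------------------------
# Gene-order fixture


def gene_order_fixture() -> tuple[list[GeneAnnotation], int]:
    """The canonical vertebrate mitochondrial gene order for a 16,500-bp
    genome (13 PCGs, 22 tRNAs, 2 rRNAs, CR between tRNA-Pro and tRNA-Phe;
    nad6 and 8 tRNAs on the negative strand).  Returns (annotations,
    genome length)."""
    from .codon_stats import read_annotations

    with resources.as_file(
        resources.files("mitobench.data").joinpath("vertebrate_mito_gene_order.tsv")
    ) as path:
        anns = read_annotations(path)
    return anns, 16500


def write_manifest(manifest: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
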