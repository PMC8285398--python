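"""Genomic interval model and set algebra.

Coordinates are 0-based, half-open (BED convention) throughout. An
:class:`IntervalSet` is an ordered collection of :class:`GenomicInterval`
optionally bound to a genome (mapping ``chrom -> length``); duplicates are
permitted until :func:`merge` is applied, so that element identity and
provenance survive set operations that are defined element-wise
(``intersect(mode="select")``, element-level subtraction in the enhancer
rules).

Distances between non-overlapping intervals are closest-edge gaps: bookended
intervals ([0,10) and [10,20)) have distance 0 but share no base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ValidationError

Genome = dict[str, int]

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: a single genomic base with a gene label."""

    gene_id: str
    chrom: str
    position: int
    strand: str = "."

    def __post_init__(self):
        if self.position < 0:
            raise ValidationError(f"TSS {self.gene_id}: negative position")


class IntervalSet:
    """Ordered collection of intervals with an optional attached genome."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Genome | None = None,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome = dict(genome) if genome is not None else None
        if self.genome is not None:
            for iv in self.intervals:
                self._check_bounds(iv)

    def _check_bounds(self, iv: GenomicInterval) -> None:
        if self.genome is None:
            return
        if iv.chrom not in self.genome:
            raise ValidationError(f"chromosome {iv.chrom!r} absent from genome")
        if iv.end > self.genome[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.genome[iv.chrom]}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=GenomicInterval.sort_key), self.genome
        )

    def chroms(self) -> list[str]:
        seen = dict.fromkeys(iv.chrom for iv in self.intervals)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        return sum(len(iv) for iv in merge(self))

    def with_genome(self, genome: Genome) -> "IntervalSet":
        return IntervalSet(self.intervals, genome)


def _shared_genome(a: IntervalSet, b: IntervalSet) -> Genome | None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValidationError("interval sets are bound to different genomes")
    return a.genome if a.genome is not None else b.genome


def _coverage_arrays(b: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged per-chromosome coverage of *b* as sorted disjoint arrays."""
    cov: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in merge(b).by_chrom().items():
        cov[chrom] = (
            np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs)),
            np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs)),
        )
    return cov


def _overlaps_coverage(iv, cov) -> bool:
    if iv.chrom not in cov:
        return False
    starts, ends = cov[iv.chrom]
    i = int(np.searchsorted(ends, iv.start, side="right"))
    return i < len(starts) and starts[i] < iv.end


def intersect(a: IntervalSet, b: IntervalSet, mode: str = "select") -> IntervalSet:
    """Intersect two interval sets.

    ``mode="select"`` returns the elements of *a* having >=1 bp overlap with
    any element of *b*, identities preserved. ``mode="segment"`` returns the
    overlapping sub-intervals (clipped against the merged coverage of *b*).
    """
    if mode not in ("select", "segment"):
        raise ValidationError(f"unknown intersect mode {mode!r}")
    genome = _shared_genome(a, b)
    cov = _coverage_arrays(b)
    out: list[GenomicInterval] = []
    if mode == "select":
        out = [iv for iv in a if _overlaps_coverage(iv, cov)]
    else:
        for iv in a:
            if iv.chrom not in cov:
                continue
            starts, ends = cov[iv.chrom]
            i = int(np.searchsorted(ends, iv.start, side="right"))
            while i < len(starts) and starts[i] < iv.end:
                s = max(iv.start, int(starts[i]))
                e = min(iv.end, int(ends[i]))
                if s < e:
                    out.append(replace(iv, start=s, end=e))
                i += 1
    return IntervalSet(out, genome)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Remove from each element of *a* all bases covered by *b*.

    Elements fully covered vanish; split elements inherit the parent's
    strand/name (provenance).
    """
    genome = _shared_genome(a, b)
    cov = _coverage_arrays(b)
    out: list[GenomicInterval] = []
    for iv in a:
        if iv.chrom not in cov:
            out.append(iv)
            continue
        starts, ends = cov[iv.chrom]
        pos = iv.start
        i = int(np.searchsorted(ends, iv.start, side="right"))
        while i < len(starts) and starts[i] < iv.end:
            s, e = int(starts[i]), int(ends[i])
            if s > pos:
                out.append(replace(iv, start=pos, end=s))
            pos = max(pos, e)
            i += 1
        if pos < iv.end:
            out.append(replace(iv, start=pos, end=iv.end))
    return IntervalSet(out, genome)


def merge(a: IntervalSet, gap: int = 0) -> IntervalSet:
    """Collapse overlapping (and bookended) intervals.

    Intervals separated by at most ``gap`` bases are collapsed; with the
    default ``gap=0`` bookended intervals merge, matching bedtools-merge
    defaults. Output is sorted and disjoint; merged intervals lose
    per-element names.
    """
    if gap < 0:
        raise ValidationError("merge gap must be >= 0")
    ivs = sorted(a.intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(out, a.genome)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Concatenate the element lists of both sets (no collapsing)."""
    genome = _shared_genome(a, b)
    return IntervalSet(list(a) + list(b), genome)


def extend(a: IntervalSet, flank: int) -> IntervalSet:
    """Grow each interval by ``flank`` bp on both sides, clipped to the genome."""
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    out = []
    for iv in a:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if a.genome is not None and iv.chrom in a.genome:
            end = min(end, a.genome[iv.chrom])
        out.append(replace(iv, start=start, end=end))
    return IntervalSet(out, a.genome)


def interval_gap(x: GenomicInterval, y: GenomicInterval) -> int | None:
    """Closest-edge gap between two intervals; 0 on overlap; None trans."""
    if x.chrom != y.chrom:
        return None
    return max(0, x.start - y.end, y.start - x.end)


def distance_to_nearest(
    query: IntervalSet, subject: IntervalSet
) -> list[tuple[int | None, int | None]]:
    """Per-query distance (bp) to the nearest subject element.

    Returns, per query element, ``(distance, subject_index)`` where the
    subject index refers to ``subject.intervals``. Overlap gives distance 0;
    ties break to the leftmost subject by (chrom, start, end). Queries on
    chromosomes without subjects get ``(None, None)``.
    """
    if len(subject) == 0:
        warnings.warn("empty subject set: all distances missing")
        return [(None, None)] * len(query)
    by_chrom: dict[str, list[tuple[GenomicInterval, int]]] = {}
    for idx, iv in enumerate(subject):
        by_chrom.setdefault(iv.chrom, []).append((iv, idx))
    arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort(key=lambda p: p[0].sort_key())
        arrays[chrom] = (
            np.array([p[0].start for p in pairs], dtype=np.int64),
            np.array([p[0].end for p in pairs], dtype=np.int64),
            [p[1] for p in pairs],
        )
    out: list[tuple[int | None, int | None]] = []
    for q in query:
        if q.chrom not in arrays:
            out.append((None, None))
            continue
        starts, ends, idxs = arrays[q.chrom]
        d = np.maximum(0, np.maximum(starts - q.end, q.start - ends))
        j = int(np.argmin(d))  # first minimum = leftmost in sorted order
        out.append((int(d[j]), idxs[j]))
    return out


def tss_windows(tss: Sequence[TssRecord], halfwidth: int, genome: Genome | None = None) -> IntervalSet:
    """Windows ``[pos - halfwidth, pos + halfwidth + 1)`` around TSS bases.

    An element overlaps a window iff its minimum base distance to the TSS
    base is <= halfwidth (strand-ignored).
    """
    if halfwidth < 0:
        raise ValidationError("halfwidth must be >= 0")
    out = []
    for t in tss:
        start = max(0, t.position - halfwidth)
        end = t.position + halfwidth + 1
        if genome is not None and t.chrom in genome:
            end = min(end, genome[t.chrom])
        out.append(GenomicInterval(t.chrom, start, end, name=t.gene_id))
    return IntervalSet(out, genome)


def tss_window_filter(
    a: IntervalSet, tss: Sequence[TssRecord], halfwidth: int
) -> IntervalSet:
    """Drop every element of *a* within ``halfwidth`` bp of a TSS base."""
    windows = tss_windows(tss, halfwidth, a.genome)
    cov = _coverage_arrays(windows)
    kept = [iv for iv in a if not _overlaps_coverage(iv, cov)]
    return IntervalSet(kept, a.genome)


# ---------------------------------------------------------------------------
# Signal tracks (bedGraph semantics) and metaprofiles
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """Per-chromosome step function: disjoint intervals with float values."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not np.isfinite(value):
                raise ValidationError(f"non-finite signal value on {chrom}")
            if start >= end or start < 0:
                raise ValidationError(f"invalid track interval {chrom}:{start}-{end}")
            per.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in per.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping track intervals on {chrom}")
            data[chrom] = (starts, ends, vals)
        return cls(data)

    def _integral(self, chrom: str, x: float) -> float:
        """Integral of the track from -inf to coordinate ``x``."""
        if chrom not in self.data:
            return 0.0
        starts, ends, vals = self.data[chrom]
        widths = (ends - starts).astype(np.float64)
        cum = np.concatenate([[0.0], np.cumsum(widths * vals)])
        i = int(np.searchsorted(starts, x, side="right"))
        total = cum[i]
        if i > 0 and x < ends[i - 1]:
            total -= (ends[i - 1] - x) * vals[i - 1]
        return float(total)

    def window_mean(self, chrom: str, lo: float, hi: float) -> float:
        """Base-weighted mean over [lo, hi); uncovered bases contribute 0."""
        if hi <= lo:
            return 0.0
        lo_c = max(lo, 0.0)
        if hi <= 0:
            return 0.0
        mass = self._integral(chrom, hi) - self._integral(chrom, lo_c)
        return mass / (hi - lo)


def aggregate_signal(
    track: SignalTrack, regions: IntervalSet, halfwidth: int, nbins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Binned metaprofile of ``track`` around region midpoints.

    Each region is represented by its midpoint +- ``halfwidth``, split into
    ``nbins`` equal bins; the bin value is the base-weighted mean of the
    track over the bin, with uncovered (or out-of-genome) bases contributing
    zero. Returns ``(matrix [n_regions x nbins], column means)``.
    """
    if nbins < 1:
        raise ValidationError("nbins must be >= 1")
    if len(regions) == 0:
        raise ValidationError("aggregate_signal requires at least one region")
    mat = np.zeros((len(regions), nbins), dtype=np.float64)
    width = 2.0 * halfwidth / nbins
    for r, iv in enumerate(regions):
        left = iv.midpoint - halfwidth
        for b in range(nbins):
            lo = left + b * width
            mat[r, b] = track.window_mean(iv.chrom, lo, lo + width)
    return mat, mat.mean(axis=0)
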