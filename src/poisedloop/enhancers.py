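"""Rule-based classification of poised, active, primed, and PoiAct enhancers.

The classes are defined combinatorially from peak sets of chromatin marks in
one or more cellular contexts (e.g. naive, serum, formative pluripotency):

* **poised** — open chromatin (ATAC or p300) overlapping regions enriched in
  both H3K27me3 and H3K4me1 in the same context, distal to TSS, and never
  overlapping H3K27ac in any context;
* **active** — the mirror image with H3K27ac and H3K27me3 roles swapped;
* **primed** — H3K4me1 regions distal to TSS carrying neither H3K27ac nor
  H3K27me3 in any context;
* **poiact** — poised elements that gain H3K27ac in a later cell state.

All fold/significance thresholds are inclusive. The per-context mark
combination is evaluated before contexts are pooled (marks are never mixed
across contexts prior to the intersection). Removal of elements carrying a
repulsive mark is element-level by default: one overlapping base kills the
whole candidate element, because the rules count unique enhancers and
base-level subtraction would fragment them. A base-level variant is kept for
cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError, ValidationError
from .intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    TssRecord,
    extend,
    intersect,
    merge,
    subtract,
    tss_window_filter,
    union,
)
from .io import PeakRecord, peaks_to_intervals

logger = logging.getLogger(__name__)

MARKS = ("ATAC", "p300", "H3K4me1", "H3K27ac", "H3K27me3", "H3K4me3")


@dataclass(frozen=True)
class MarkFilter:
    """Thresholds and processing for one mark's peak set."""

    min_fold: float = 0.0
    max_q: float | None = None
    max_p: float | None = None
    extension: int = 0

    def __post_init__(self):
        if self.min_fold < 0 or self.extension < 0:
            raise ValidationError("thresholds must be >= 0")


@dataclass
class CallingParams:
    """Parameters of the enhancer-calling rules.

    Defaults follow the reference protocol: narrow open-chromatin peaks at
    q <= 0.05 with fold enrichment >= 4; broad histone peaks at q <= 0.1
    with fold >= 5 (H3K27ac) or >= 2 (H3K4me1, H3K27me3), extended +-1 kb;
    TSS proximity window +-5 kb; de novo calling extends histone peaks
    +-2.5 kb and requires strictly >10 kb TSS distance.
    """

    tss_halfwidth: int = 5000
    distal_min: int = 10000
    denovo_extension: int = 2500
    element_level_subtraction: bool = True
    tss_filter_first: bool = True
    filters: dict[str, MarkFilter] = field(default_factory=dict)

    def __post_init__(self):
        if self.tss_halfwidth < 0 or self.distal_min < 0:
            raise ValidationError("window sizes must be >= 0")
        defaults = {
            "ATAC": MarkFilter(min_fold=4.0, max_q=0.05),
            "p300": MarkFilter(min_fold=4.0, max_q=0.05),
            "H3K27ac": MarkFilter(min_fold=5.0, max_q=0.1, extension=1000),
            "H3K4me1": MarkFilter(min_fold=2.0, max_q=0.1, extension=1000),
            "H3K27me3": MarkFilter(min_fold=2.0, max_q=0.1, extension=1000),
            "H3K4me3": MarkFilter(min_fold=0.0, max_q=0.1, extension=1000),
        }
        defaults.update(self.filters)
        self.filters = defaults


class MarkLibrary:
    """Peak collections keyed by ``(context, mark)``."""

    def __init__(self, genome: Genome | None = None):
        self.genome = genome
        self._peaks: dict[tuple[str, str], list[PeakRecord]] = {}

    def add(self, context: str, mark: str, peaks: Sequence[PeakRecord]) -> None:
        self._peaks[(context, mark)] = list(peaks)

    def has(self, context: str, mark: str) -> bool:
        return (context, mark) in self._peaks

    def get(self, context: str, mark: str) -> list[PeakRecord]:
        try:
            return self._peaks[(context, mark)]
        except KeyError:
            raise ConfigurationError(
                f"context {context!r} is missing required mark {mark!r}"
            ) from None

    def contexts(self) -> list[str]:
        return sorted({c for c, _ in self._peaks})

    def items(self):
        return self._peaks.items()


@dataclass(frozen=True)
class EnhancerCall:
    interval: GenomicInterval
    enhancer_class: str
    source_contexts: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()


def calls_to_intervals(calls: Sequence[EnhancerCall], genome=None) -> IntervalSet:
    return IntervalSet([c.interval for c in calls], genome)


def filter_peaks(
    peaks: Sequence[PeakRecord],
    min_fold: float = 0.0,
    max_q: float | None = None,
    max_p: float | None = None,
) -> list[PeakRecord]:
    """Retain peaks with fold_enrichment >= min_fold and significant p/q.

    Comparisons are inclusive. A peak with a missing q (or p) value is
    dropped when the corresponding threshold is enabled.
    """
    if min_fold < 0:
        raise ValidationError("min_fold must be >= 0")
    out = []
    for p in peaks:
        if p.fold_enrichment < min_fold:
            continue
        if max_q is not None and (p.q_value is None or p.q_value > max_q):
            continue
        if max_p is not None and (p.p_value is None or p.p_value > max_p):
            continue
        out.append(p)
    if len(out) < len(peaks):
        logger.debug("filter_peaks dropped %d/%d records", len(peaks) - len(out), len(peaks))
    return out


def _mark_regions(
    marks: MarkLibrary, context: str, mark: str, flt: MarkFilter
) -> IntervalSet:
    peaks = filter_peaks(marks.get(context, mark), flt.min_fold, flt.max_q, flt.max_p)
    ivs = peaks_to_intervals(peaks, marks.genome)
    if flt.extension:
        ivs = extend(ivs, flt.extension)
    return ivs


def element_subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Remove every element of *a* having >=1 bp overlap with *b*."""
    hit = {id(iv) for iv in intersect(a, b, mode="select")}
    return IntervalSet([iv for iv in a if id(iv) not in hit], a.genome)


def _remove_marked(a: IntervalSet, marked: IntervalSet, element_level: bool) -> IntervalSet:
    return element_subtract(a, marked) if element_level else subtract(a, marked)


def _open_mark(marks: MarkLibrary, context: str) -> str:
    if marks.has(context, "ATAC"):
        return "ATAC"
    return "p300"


def _union_mark_regions(
    marks: MarkLibrary, contexts: Sequence[str], mark: str, flt: MarkFilter
) -> IntervalSet:
    acc = IntervalSet([], marks.genome)
    for c in contexts:
        if marks.has(c, mark):
            acc = union(acc, _mark_regions(marks, c, mark, flt))
    return acc


def _call_combinatorial(
    marks: MarkLibrary,
    contexts: Sequence[str],
    tss: Sequence[TssRecord],
    params: CallingParams,
    require_mark: str,
    subtract_mark: str,
    label: str,
) -> list[EnhancerCall]:
    """Shared body of the poised/active in vitro rules.

    Per context: open-chromatin peaks overlapping the segment intersection
    of extended ``require_mark`` and extended H3K4me1 regions; candidates
    are pooled across contexts, TSS-filtered, purged of elements carrying
    ``subtract_mark`` in any context, and merged.
    """
    if not contexts:
        logger.warning("%s calling invoked with no contexts", label)
        return []
    provenance: list[str] = []
    candidates = IntervalSet([], marks.genome)
    per_interval_context: dict[tuple, str] = {}
    for c in contexts:
        open_mark = _open_mark(marks, c)
        open_iv = _mark_regions(marks, c, open_mark, params.filters[open_mark])
        req = _mark_regions(marks, c, require_mark, params.filters[require_mark])
        k4 = _mark_regions(marks, c, "H3K4me1", params.filters["H3K4me1"])
        both = intersect(req, k4, mode="segment")
        cand = intersect(open_iv, both, mode="select")
        provenance.append(
            f"{c}: {open_mark} INTERSECT ({require_mark} AND H3K4me1) -> {len(cand)}"
        )
        for iv in cand:
            per_interval_context[(iv.chrom, iv.start, iv.end)] = c
        candidates = union(candidates, cand)
    steps = [f"UNION across contexts -> {len(candidates)}"]

    sub_regions = _union_mark_regions(marks, contexts, subtract_mark, params.filters[subtract_mark])

    def tss_step(ivs):
        out = tss_window_filter(ivs, tss, params.tss_halfwidth)
        steps.append(f"TSS +-{params.tss_halfwidth} filter -> {len(out)}")
        return out

    def sub_step(ivs):
        out = _remove_marked(ivs, sub_regions, params.element_level_subtraction)
        steps.append(f"SUBTRACT {subtract_mark} union -> {len(out)}")
        return out

    if params.tss_filter_first:
        candidates = sub_step(tss_step(candidates))
    else:
        candidates = tss_step(sub_step(candidates))
    final = merge(candidates)
    steps.append(f"MERGE -> {len(final)}")
    prov = tuple(provenance + steps)
    return [
        EnhancerCall(iv, label, tuple(contexts), prov) for iv in final
    ]


def call_poised_invitro(marks, contexts, tss, params: CallingParams) -> list[EnhancerCall]:
    """Poised: open chromatin + H3K27me3 + H3K4me1, distal, no H3K27ac."""
    return _call_combinatorial(marks, contexts, tss, params, "H3K27me3", "H3K27ac", "poised")


def call_active_invitro(marks, contexts, tss, params: CallingParams) -> list[EnhancerCall]:
    """Active: open chromatin + H3K27ac + H3K4me1, distal, no H3K27me3."""
    return _call_combinatorial(marks, contexts, tss, params, "H3K27ac", "H3K27me3", "active")


def call_primed_invitro(marks, contexts, tss, params: CallingParams) -> list[EnhancerCall]:
    """Primed: H3K4me1 regions distal to TSS lacking both H3K27ac and H3K27me3."""
    if not contexts:
        logger.warning("primed calling invoked with no contexts")
        return []
    k4 = _union_mark_regions(marks, contexts, "H3K4me1", params.filters["H3K4me1"])
    steps = [f"UNION H3K4me1 across contexts -> {len(k4)}"]
    k27me3 = _union_mark_regions(marks, contexts, "H3K27me3", params.filters["H3K27me3"])
    k27ac = _union_mark_regions(marks, contexts, "H3K27ac", params.filters["H3K27ac"])
    cand = tss_window_filter(k4, tss, params.tss_halfwidth)
    steps.append(f"TSS +-{params.tss_halfwidth} filter -> {len(cand)}")
    cand = _remove_marked(cand, k27me3, params.element_level_subtraction)
    steps.append(f"SUBTRACT H3K27me3 union -> {len(cand)}")
    cand = _remove_marked(cand, k27ac, params.element_level_subtraction)
    steps.append(f"SUBTRACT H3K27ac union -> {len(cand)}")
    final = merge(cand)
    steps.append(f"MERGE -> {len(final)}")
    return [EnhancerCall(iv, "primed", tuple(contexts), tuple(steps)) for iv in final]


def resolve_class_overlaps(
    poised: Sequence[EnhancerCall],
    active: Sequence[EnhancerCall],
    primed: Sequence[EnhancerCall],
) -> dict[str, list[EnhancerCall]]:
    """Make the three classes pairwise disjoint by overlap.

    Elements overlapping between poised and either other class are removed
    from both sets; elements overlapping between active and primed are kept
    in the active category only.
    """
    p_iv = calls_to_intervals(poised)
    a_iv = calls_to_intervals(active)
    r_iv = calls_to_intervals(primed)

    def overlapping_ids(src: IntervalSet, other: IntervalSet) -> set[int]:
        return {id(iv) for iv in intersect(src, other, mode="select")}

    p_drop = overlapping_ids(p_iv, a_iv) | overlapping_ids(p_iv, r_iv)
    a_drop = overlapping_ids(a_iv, p_iv)
    r_drop = overlapping_ids(r_iv, p_iv) | overlapping_ids(r_iv, a_iv)

    def keep(calls, ivset, drop):
        return [c for c, iv in zip(calls, ivset) if id(iv) not in drop]

    return {
        "poised": keep(poised, p_iv, p_drop),
        "active": keep(active, a_iv, a_drop),
        "primed": keep(primed, r_iv, r_drop),
    }


@dataclass
class LaterAcSet:
    """A later-stage H3K27ac peak set; replicates are INTERSECTed first."""

    replicates: list[list[PeakRecord]]
    min_fold: float = 5.0
    max_q: float | None = 0.1
    max_p: float | None = None
    extension: int = 1000
    label: str = "later"


def call_poiact(
    poised: Sequence[EnhancerCall],
    later_sets: Sequence[LaterAcSet],
    genome: Genome | None = None,
) -> tuple[list[EnhancerCall], list[EnhancerCall]]:
    """Split poised calls into (poiact, still-poised) by later H3K27ac gain."""
    acquired = IntervalSet([], genome)
    for ls in later_sets:
        reps = [
            peaks_to_intervals(
                filter_peaks(r, ls.min_fold, ls.max_q, ls.max_p), genome
            )
            for r in ls.replicates
        ]
        if not reps:
            continue
        regions = reps[0]
        for r in reps[1:]:
            regions = intersect(regions, r, mode="segment")
        if ls.extension:
            regions = extend(regions, ls.extension)
        acquired = union(acquired, regions)
    p_iv = calls_to_intervals(poised, genome)
    hit = {id(iv) for iv in intersect(p_iv, acquired, mode="select")}
    poiact, still = [], []
    for c, iv in zip(poised, p_iv):
        if id(iv) in hit:
            poiact.append(
                EnhancerCall(c.interval, "poiact", c.source_contexts,
                             c.provenance + ("gained later H3K27ac",))
            )
        else:
            still.append(c)
    return poiact, still


def call_poised_invivo(
    atac: Sequence[PeakRecord],
    k27me3: Sequence[PeakRecord],
    k27ac_invivo: Sequence[PeakRecord],
    k27ac_invitro_union: IntervalSet,
    tss: Sequence[TssRecord],
    genome: Genome | None = None,
    *,
    atac_min_fold: float = 5.0,
    atac_max_q: float = 0.05,
    histone_min_fold: float = 2.0,
    histone_max_p: float = 0.01,
    extension: int = 1000,
    tss_halfwidth: int = 5000,
    element_level: bool = True,
) -> list[EnhancerCall]:
    """In vivo (epiblast) poised calls: no H3K4me1 requirement, p-value
    thresholds on histone marks, subtraction of both in vivo and in vitro
    H3K27ac, TSS filter applied last."""
    open_iv = peaks_to_intervals(filter_peaks(atac, atac_min_fold, max_q=atac_max_q), genome)
    k27me3_iv = extend(
        peaks_to_intervals(
            filter_peaks(k27me3, histone_min_fold, max_p=histone_max_p), genome
        ),
        extension,
    )
    cand = intersect(open_iv, k27me3_iv, mode="select")
    k27ac_iv = peaks_to_intervals(
        filter_peaks(k27ac_invivo, histone_min_fold, max_p=histone_max_p), genome
    )
    marked = union(k27ac_iv, k27ac_invitro_union)
    cand = element_subtract(cand, marked) if element_level else subtract(cand, marked)
    cand = tss_window_filter(cand, tss, tss_halfwidth)
    final = merge(cand)
    prov = (
        f"ATAC(fold>={atac_min_fold},q<={atac_max_q}) INTERSECT "
        f"H3K27me3(fold>={histone_min_fold},p<={histone_max_p},+-{extension})",
        "SUBTRACT in vivo + in vitro H3K27ac",
        f"TSS +-{tss_halfwidth} filter",
        f"MERGE -> {len(final)}",
    )
    return [EnhancerCall(iv, "poised", ("invivo",), prov) for iv in final]


def call_poised_denovo(
    open_peaks: Sequence[PeakRecord],
    k27me3: Sequence[PeakRecord],
    k27ac: Sequence[PeakRecord] | None,
    tss: Sequence[TssRecord],
    genome: Genome | None = None,
    *,
    open_min_fold: float = 3.0,
    k27me3_min_fold: float = 3.0,
    k27ac_min_fold: float = 3.0,
    max_q: float = 0.1,
    extension: int = 2500,
    distal_min: int = 10000,
    element_level: bool = True,
) -> list[EnhancerCall]:
    """De novo poised calls for a species with sparse data.

    Histone peaks are extended +-``extension`` (default 2.5 kb), the open
    chromatin peaks intersected against them, and only elements strictly
    more than ``distal_min`` bp from any TSS base are kept. H3K27ac
    subtraction is skipped with a notice when no H3K27ac data exists.
    """
    open_iv = peaks_to_intervals(filter_peaks(open_peaks, open_min_fold, max_q=max_q), genome)
    k27me3_iv = extend(
        peaks_to_intervals(filter_peaks(k27me3, k27me3_min_fold, max_q=max_q), genome),
        extension,
    )
    cand = intersect(open_iv, k27me3_iv, mode="select")
    # strict > distal_min: the +-distal_min window (inclusive at the edge)
    # removes elements whose minimum base distance is <= distal_min
    cand = tss_window_filter(cand, tss, distal_min)
    prov = [
        f"open(fold>={open_min_fold},q<={max_q}) INTERSECT "
        f"H3K27me3(fold>={k27me3_min_fold},q<={max_q},+-{extension})",
        f"distal filter: >{distal_min} bp from TSS",
    ]
    if k27ac is not None:
        k27ac_iv = extend(
            peaks_to_intervals(filter_peaks(k27ac, k27ac_min_fold, max_q=max_q), genome),
            extension,
        )
        cand = element_subtract(cand, k27ac_iv) if element_level else subtract(cand, k27ac_iv)
        prov.append("SUBTRACT H3K27ac")
    else:
        logger.info("de novo calling: no H3K27ac available, subtraction skipped")
        prov.append("H3K27ac unavailable: subtraction skipped")
    final = merge(cand)
    prov.append(f"MERGE -> {len(final)}")
    return [EnhancerCall(iv, "poised", ("denovo",), tuple(prov)) for iv in final]


def set_overlap_report(
    a: Sequence[EnhancerCall] | IntervalSet, b: Sequence[EnhancerCall] | IntervalSet
) -> dict:
    """Overlap (>=1 bp) counts and percentages in both directions."""

    def as_ivset(x):
        if isinstance(x, IntervalSet):
            return x
        return calls_to_intervals(list(x))

    a_iv, b_iv = as_ivset(a), as_ivset(b)
    a_hit = len(intersect(a_iv, b_iv, mode="select"))
    b_hit = len(intersect(b_iv, a_iv, mode="select"))
    pct = lambda n, d: round(100.0 * n / d, 2) if d else 0.0
    return {
        "n_a": len(a_iv),
        "n_b": len(b_iv),
        "a_in_b": a_hit,
        "b_in_a": b_hit,
        "pct_a_in_b": pct(a_hit, len(a_iv)),
        "pct_b_in_a": pct(b_hit, len(b_iv)),
    }
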