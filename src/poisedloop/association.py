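"""Association statistics linking enhancers to CpG islands, promoter
chromatin states, and gene assignments.

The Fisher exact test reports the sample (cross-product) odds ratio
``(a*d)/(b*c)`` and the conventional two-sided p value obtained by summing
hypergeometric probabilities no larger than the observed table's. The
rank-sum comparison uses the exact Wilcoxon/Mann-Whitney null distribution
for small tie-free samples and the tie/continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .intervals import (
    IntervalSet,
    TssRecord,
    distance_to_nearest,
    intersect,
    merge,
    tss_windows,
)

PROMOTER_STATES = ("bivalent", "k27me3_only", "k4me3_only", "unmarked")


def cgi_distance_profile(
    enhancers: IntervalSet, cgis: IntervalSet
) -> tuple[list[int | None], float]:
    """Per-enhancer distance to the nearest CpG island + overlap percentage.

    The overlap fraction is the share of enhancers at distance 0, reported
    as a percentage rounded to two decimals.
    """
    if len(cgis) == 0:
        warnings.warn("empty CGI set: all distances missing")
        return [None] * len(enhancers), 0.0
    dists = [d for d, _ in distance_to_nearest(enhancers, cgis)]
    known = [d for d in dists if d is not None]
    frac = round(100.0 * sum(1 for d in known if d == 0) / len(enhancers), 2) if enhancers else 0.0
    return dists, frac


def compare_distributions(
    x: Sequence[float],
    y: Sequence[float],
    center: str = "mean",
    exact_max_n: int = 25,
) -> tuple[float, float | None]:
    """Two-sided rank-sum p value and fold change of centers of x over y.

    The exact null distribution is used when the combined sample size is at
    most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections. ``center`` selects
    mean (default) or median for the fold change.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("samples must be finite")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(1.0, res.pvalue))
    cf = np.mean if center == "mean" else np.median
    denom = cf(y)
    fc = float(cf(x) / denom) if denom != 0 else None
    return p, fc


@dataclass(frozen=True)
class PromoterState:
    gene_id: str
    state: str


def classify_promoter_states(
    tss: Sequence[TssRecord],
    k4me3_peaks: IntervalSet,
    k27me3_peaks: IntervalSet,
    window_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Classify each promoter by H3K4me3/H3K27me3 overlap of its TSS window.

    Both marks -> bivalent; only H3K27me3 -> k27me3_only; only H3K4me3 ->
    k4me3_only; neither -> unmarked. Default window is TSS +-1 kb.
    """
    if window_halfwidth <= 0:
        raise ValidationError("window_halfwidth must be > 0")
    ids = [t.gene_id for t in tss]
    dupes = {g for g in ids if ids.count(g) > 1} if len(set(ids)) != len(ids) else set()
    if dupes:
        raise ValidationError(f"duplicate gene ids: {sorted(dupes)}")
    windows = tss_windows(tss, window_halfwidth)
    k4_hit = {w.name for w in intersect(windows, k4me3_peaks, mode="select")}
    k27_hit = {w.name for w in intersect(windows, k27me3_peaks, mode="select")}
    rows = []
    for t in tss:
        k4, k27 = t.gene_id in k4_hit, t.gene_id in k27_hit
        state = (
            "bivalent" if (k4 and k27)
            else "k27me3_only" if k27
            else "k4me3_only" if k4
            else "unmarked"
        )
        rows.append({"gene_id": t.gene_id, "state": state})
    return pd.DataFrame(rows, columns=["gene_id", "state"])


@dataclass
class Fisher2x2:
    """2x2 enrichment table: a=cat&hit, b=cat&miss, c=other&hit, d=other&miss."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float | None
    p_two_sided: float


def enrichment_fisher(
    hit_flags: Sequence[bool], category_flags: Sequence[bool]
) -> Fisher2x2:
    """Fisher exact enrichment of ``category`` among ``hit`` over one universe."""
    hit = np.asarray(hit_flags, dtype=bool)
    cat = np.asarray(category_flags, dtype=bool)
    if hit.shape != cat.shape:
        raise ValidationError("flag vectors must have equal length")
    a = int(np.sum(cat & hit))
    b = int(np.sum(cat & ~hit))
    c = int(np.sum(~cat & hit))
    d = int(np.sum(~cat & ~hit))
    return fisher_from_counts(a, b, c, d)


def fisher_from_counts(a: int, b: int, c: int, d: int) -> Fisher2x2:
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 table: a margin is zero")
        return Fisher2x2(a, b, c, d, None, 1.0)
    odds = (a * d) / (b * c) if b * c > 0 else (0.0 if a * d == 0 else float("inf"))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return Fisher2x2(a, b, c, d, float(odds), float(p))


def call_pcg_domains(
    eed_replicates: Sequence[IntervalSet],
    ring1b_replicates: Sequence[IntervalSet],
) -> IntervalSet:
    """Polycomb domains: bases bound by both EED and RING1B.

    Replicate peak sets of each factor are segment-intersected first, then
    the two factors' consensus regions are intersected and merged.
    """
    if not eed_replicates or not ring1b_replicates:
        raise ValidationError("both factors need at least one replicate set")

    def consensus(reps):
        acc = reps[0]
        for r in reps[1:]:
            acc = intersect(acc, r, mode="segment")
        return acc

    eed = consensus(list(eed_replicates))
    ring = consensus(list(ring1b_replicates))
    return merge(intersect(eed, ring, mode="segment"))


def assign_nearest_gene(
    enhancers: IntervalSet, tss: Sequence[TssRecord]
) -> pd.DataFrame:
    """Link each enhancer to the gene with the nearest TSS.

    Distance is |enhancer midpoint - TSS position|; ties break to the
    leftmost TSS by (chrom, position).
    """
    if not tss:
        raise ValidationError("TSS set must be non-empty")
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.position)
    rows = []
    for iv in enhancers:
        cands = by_chrom.get(iv.chrom)
        if not cands:
            rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                         "gene_id": None, "distance": None})
            continue
        mid = iv.midpoint
        d = np.array([abs(t.position - mid) for t in cands])
        j = int(np.argmin(d))  # first minimum = leftmost (positions sorted)
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "gene_id": cands[j].gene_id, "distance": int(d[j])})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "distance"])
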