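"""Chromatin-loop lists: filtering, size distributions, anchor annotation,
TAD classification, and loop-set comparison.

A loop is a pair of cis anchors; its size is the distance between anchor
midpoints, which makes the measure invariant to anchor width. Anchor/TAD
membership uses anchor midpoints so an anchor straddling a TAD boundary
belongs to exactly one TAD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    TssRecord,
    extend,
    intersect,
    merge,
    tss_window_filter,
    tss_windows,
)

logger = logging.getLogger(__name__)

DEFAULT_SIZE_EDGES = (0, 300_000, 1_000_000)  # short / mid-range / long


@dataclass(frozen=True)
class Loop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    p_value: float | None = None
    q_value: float | None = None
    pet_count: int | None = None

    def __post_init__(self):
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValidationError("loop anchors must be cis")
        if self.anchor1.end > self.anchor2.start:
            raise ValidationError(
                "anchors overlap or are mis-ordered after canonicalisation"
            )

    @property
    def size(self) -> int:
        return self.anchor2.midpoint - self.anchor1.midpoint

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


class LoopSet:
    def __init__(self, loops: Sequence[Loop] = (), genome: Genome | None = None):
        self.loops = list(loops)
        self.genome = genome

    def __len__(self):
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)

    def __getitem__(self, i):
        return self.loops[i]

    def anchors(self, which: str = "both") -> IntervalSet:
        out = []
        for lp in self.loops:
            if which in ("both", "left"):
                out.append(lp.anchor1)
            if which in ("both", "right"):
                out.append(lp.anchor2)
        return IntervalSet(out, self.genome)


def read_bedpe(
    path,
    column_map: Mapping[str, int] | None = None,
    genome: Genome | None = None,
) -> LoopSet:
    """Read a BEDPE loop list.

    ``column_map`` assigns 0-based extra-column indices to ``p``, ``q`` and
    ``pet``. Anchors are canonically ordered left-to-right; trans pairs are
    excluded with a logged count.
    """
    column_map = dict(column_map or {})
    loops: list[Loop] = []
    n_trans = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE requires >=6 columns")
            if f[0] != f[3]:
                n_trans += 1
                continue
            a = GenomicInterval(f[0], int(f[1]), int(f[2]))
            b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            if b.start < a.start:
                a, b = b, a

            def col(key):
                if key not in column_map:
                    return None
                v = f[column_map[key]]
                return None if v in (".", "") else float(v)

            try:
                loops.append(
                    Loop(
                        a, b,
                        p_value=col("p"),
                        q_value=col("q"),
                        pet_count=int(col("pet")) if col("pet") is not None else None,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if n_trans:
        logger.info("read_bedpe: excluded %d trans pairs", n_trans)
    return LoopSet(loops, genome)


def write_bedpe(path, loops: LoopSet) -> None:
    """Write BEDPE with pet/p/q in columns 7-9 ('.' for missing)."""
    fmt = lambda v: "." if v is None else (f"{v:g}" if isinstance(v, float) else str(v))
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                "\t".join(
                    [
                        lp.anchor1.chrom, str(lp.anchor1.start), str(lp.anchor1.end),
                        lp.anchor2.chrom, str(lp.anchor2.start), str(lp.anchor2.end),
                        fmt(lp.pet_count), fmt(lp.p_value), fmt(lp.q_value),
                    ]
                )
                + "\n"
            )


def filter_loops(
    loops: LoopSet, max_p: float | None = None, max_q: float | None = None
) -> LoopSet:
    """Keep loops whose chosen significance value is <= the threshold."""
    if (max_p is None) == (max_q is None):
        raise ConfigurationError("specify exactly one of max_p / max_q")
    key, thr = ("p_value", max_p) if max_p is not None else ("q_value", max_q)
    vals = [getattr(lp, key) for lp in loops]
    if any(v is None for v in vals):
        raise ConfigurationError(f"cannot filter on missing {key} column")
    return LoopSet([lp for lp, v in zip(loops, vals) if v <= thr], loops.genome)


def loop_size_distribution(
    loops: LoopSet, bin_edges: Sequence[int] = DEFAULT_SIZE_EDGES
) -> np.ndarray:
    """Histogram of loop sizes over half-open [lo, hi) bins.

    ``bin_edges`` are the left edges of each bin; the last bin is unbounded.
    A size equal to an edge falls in the upper bin.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing")
    sizes = np.array([lp.size for lp in loops], dtype=np.int64)
    counts = np.zeros(len(edges), dtype=np.int64)
    if len(sizes):
        idx = np.searchsorted(edges, sizes, side="right") - 1
        for i in idx[idx >= 0]:
            counts[i] += 1
    return counts


@dataclass
class AnnotationHierarchy:
    """Ordered partner categories: first matching feature set wins.

    Each entry is ``(label, IntervalSet)``; a terminal fallback label (with
    ``None`` features) catches everything else.
    """

    categories: list[tuple[str, IntervalSet | None]]

    def __post_init__(self):
        if not self.categories:
            raise ConfigurationError("annotation hierarchy may not be empty")
        if self.categories[-1][1] is not None:
            self.categories = self.categories + [("other", None)]


def default_hierarchy(
    tss: Sequence[TssRecord],
    seeds: IntervalSet,
    pcg_domains: IntervalSet | None = None,
    tss_halfwidth: int = 7500,
) -> AnnotationHierarchy:
    """Promoter (TSS +-7.5 kb) > seed-class element > PcG domain > other."""
    cats: list[tuple[str, IntervalSet | None]] = [
        ("promoter", tss_windows(tss, tss_halfwidth)),
        ("seed", seeds),
    ]
    if pcg_domains is not None:
        cats.append(("pcg_domain", pcg_domains))
    cats.append(("other", None))
    return AnnotationHierarchy(cats)


def annotate_partner(
    loops: LoopSet,
    seeds: IntervalSet,
    hierarchy: AnnotationHierarchy,
    anchor_ext: int = 10000,
) -> pd.DataFrame:
    """Hierarchically annotate the partner of every seed-touching loop.

    A loop is selected when at least one anchor, extended by
    ``anchor_ext``, overlaps a seed element. The non-seed (partner) anchor
    is tested against the hierarchy's feature sets in order; the first hit
    labels the loop. Loops whose two anchors both touch seeds contribute
    one row per seed-anchor orientation, and their partner anchor (itself a
    seed) falls into the seed-element category unless an earlier category
    matches. Returns one row per (loop, seed-anchor orientation) with the
    category label and anchor coordinates.
    """
    seed_cov = merge(seeds)

    def hits_seed(anchor: GenomicInterval) -> bool:
        ext = IntervalSet([anchor])
        return len(intersect(extend(ext, anchor_ext), seed_cov, mode="select")) > 0

    def categorize(anchor: GenomicInterval) -> str:
        for label, feats in hierarchy.categories:
            if feats is None:
                return label
            if len(intersect(IntervalSet([anchor]), feats, mode="select")) > 0:
                return label
        return hierarchy.categories[-1][0]

    rows = []
    for i, lp in enumerate(loops):
        s1, s2 = hits_seed(lp.anchor1), hits_seed(lp.anchor2)
        if s1:
            rows.append((i, "anchor1", lp.anchor2, categorize(lp.anchor2)))
        if s2:
            rows.append((i, "anchor2", lp.anchor1, categorize(lp.anchor1)))
    return pd.DataFrame(
        [
            {
                "loop_index": i,
                "seed_anchor": side,
                "partner_chrom": a.chrom,
                "partner_start": a.start,
                "partner_end": a.end,
                "category": cat,
            }
            for i, side, a, cat in rows
        ],
        columns=[
            "loop_index", "seed_anchor", "partner_chrom", "partner_start",
            "partner_end", "category",
        ],
    )


class TadSet:
    """Disjoint TAD intervals per chromosome."""

    def __init__(self, tads: IntervalSet):
        merged_len = sum(len(iv) for iv in merge(tads))
        raw_len = sum(len(iv) for iv in tads)
        if merged_len != raw_len:
            raise ValidationError("TADs must be disjoint within a chromosome")
        self.tads = tads.sorted()
        self._by_chrom = {
            chrom: (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
            for chrom, ivs in self.tads.by_chrom().items()
        }

    def locate(self, chrom: str, pos: int) -> int | None:
        """Index (within the sorted set) of the TAD containing ``pos``."""
        if chrom not in self._by_chrom:
            return None
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            offset = sum(
                len(v[0]) for c, v in sorted(self._by_chrom.items()) if c < chrom
            )
            return offset + i
        return None


def classify_tad_status(loops: LoopSet, tads: TadSet) -> tuple[list[str], dict]:
    """Label each loop intra/inter/unassigned by anchor-midpoint TAD membership.

    Both midpoints in the same TAD -> intra; in two different TADs ->
    inter; either midpoint outside all TADs -> unassigned (excluded from
    the reported intra/inter fractions).
    """
    labels = []
    for lp in loops:
        t1 = tads.locate(lp.chrom, lp.anchor1.midpoint)
        t2 = tads.locate(lp.chrom, lp.anchor2.midpoint)
        if t1 is None or t2 is None:
            labels.append("unassigned")
        elif t1 == t2:
            labels.append("intra")
        else:
            labels.append("inter")
    n_intra = labels.count("intra")
    n_inter = labels.count("inter")
    assigned = n_intra + n_inter
    fractions = {
        "n_intra": n_intra,
        "n_inter": n_inter,
        "n_unassigned": labels.count("unassigned"),
        "pct_intra": round(100.0 * n_intra / assigned, 2) if assigned else None,
        "pct_inter": round(100.0 * n_inter / assigned, 2) if assigned else None,
    }
    return labels, fractions


def loopset_overlap(a: LoopSet, b: LoopSet, anchor_ext: int = 10000) -> float:
    """Percentage of loops of *a* matched in *b* under anchor extension.

    A loop of *a* is matched when some loop of *b* (canonical orientation)
    has its anchor1 overlapping a.anchor1 extended by ``anchor_ext`` AND
    its anchor2 overlapping a.anchor2 extended likewise. The measure is
    directional (not symmetric in a and b).
    """
    if len(a) == 0:
        return 0.0
    by_chrom: dict[str, list[Loop]] = {}
    for lp in b:
        by_chrom.setdefault(lp.chrom, []).append(lp)
    n_matched = 0
    for lp in a:
        lo1, hi1 = lp.anchor1.start - anchor_ext, lp.anchor1.end + anchor_ext
        lo2, hi2 = lp.anchor2.start - anchor_ext, lp.anchor2.end + anchor_ext
        for cand in by_chrom.get(lp.chrom, ()):
            if (
                cand.anchor1.start < hi1
                and lo1 < cand.anchor1.end
                and cand.anchor2.start < hi2
                and lo2 < cand.anchor2.end
            ):
                n_matched += 1
                break
    return round(100.0 * n_matched / len(a), 2)


def interaction_summary(
    loops: LoopSet,
    pes: IntervalSet,
    tss: Sequence[TssRecord],
    anchor_ext: int = 10000,
    tss_halfwidth: int = 7500,
    distal_min: int = 10000,
) -> dict:
    """Summaries of enhancer participation in loops.

    Computes the distal enhancer subset (strictly more than ``distal_min``
    bp from any TSS base), the fraction of distal enhancers appearing in at
    least one loop anchor (+- ``anchor_ext``), the fraction of those
    interactions whose partner anchor holds a promoter (TSS +-
    ``tss_halfwidth``), and the list of interacting gene ids.
    """
    distal = tss_window_filter(pes, tss, distal_min)
    promoter_windows = tss_windows(tss, tss_halfwidth)
    ext_anchors1 = [
        extend(IntervalSet([lp.anchor1]), anchor_ext)[0] for lp in loops
    ]
    ext_anchors2 = [
        extend(IntervalSet([lp.anchor2]), anchor_ext)[0] for lp in loops
    ]

    def overlaps_any(iv, others: IntervalSet) -> bool:
        return len(intersect(IntervalSet([iv]), others, mode="select")) > 0

    pe_cov = merge(distal)
    interacting_pe_ids = set()
    n_interactions = 0
    n_promoter = 0
    interacting_genes: set[str] = set()
    for lp, e1, e2 in zip(loops, ext_anchors1, ext_anchors2):
        for seed_anchor, partner in ((e1, lp.anchor2), (e2, lp.anchor1)):
            if not overlaps_any(seed_anchor, pe_cov):
                continue
            n_interactions += 1
            hit_windows = intersect(
                promoter_windows, IntervalSet([partner]), mode="select"
            )
            if len(hit_windows) > 0:
                n_promoter += 1
                interacting_genes.update(w.name for w in hit_windows)
            for pe in intersect(distal, IntervalSet([seed_anchor]), mode="select"):
                interacting_pe_ids.add((pe.chrom, pe.start, pe.end))
    n_distal = len(distal)
    n_interacting = len(
        {
            (pe.chrom, pe.start, pe.end)
            for pe in distal
            if (pe.chrom, pe.start, pe.end) in interacting_pe_ids
        }
    )
    return {
        "n_distal_pes": n_distal,
        "n_interacting_pes": n_interacting,
        "pct_pes_interacting": round(100.0 * n_interacting / n_distal, 2)
        if n_distal
        else None,
        "n_interactions": n_interactions,
        "n_promoter_interactions": n_promoter,
        "pct_interactions_with_promoter": round(
            100.0 * n_promoter / n_interactions, 2
        )
        if n_interactions
        else None,
        "interacting_genes": sorted(interacting_genes),
    }
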