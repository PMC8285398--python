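"""Independent brute-force oracles used by the test suite.

Everything here works on explicit per-base boolean arrays or exhaustive
enumeration, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from poisedloop.intervals import GenomicInterval, IntervalSet

# ---------------------------------------------------------------------------
# per-base set algebra on a single small chromosome
# ---------------------------------------------------------------------------


def coverage_mask(ivs, chrom_len: int, chrom: str = "chr1") -> np.ndarray:
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in ivs:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str = "chr1") -> list[GenomicInterval]:
    out = []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def naive_segment_intersect(a, b, chrom_len):
    """Per-element clipping of each a-element against b's base coverage."""
    bmask = coverage_mask(b, chrom_len)
    out = []
    for iv in a:
        m = np.zeros(chrom_len, dtype=bool)
        m[iv.start : iv.end] = True
        out.extend(mask_to_intervals(m & bmask))
    return out


def naive_subtract(a, b, chrom_len):
    bmask = coverage_mask(b, chrom_len)
    out = []
    for iv in a:
        m = np.zeros(chrom_len, dtype=bool)
        m[iv.start : iv.end] = True
        out.extend(mask_to_intervals(m & ~bmask))
    return out


def naive_select(a, b, chrom_len):
    bmask = coverage_mask(b, chrom_len)
    return [iv for iv in a if bmask[iv.start : iv.end].any()]


def naive_merge(a, chrom_len, gap: int = 0):
    """Coverage runs, with gaps <= ``gap`` bridged."""
    mask = coverage_mask(a, chrom_len)
    if gap > 0:
        runs = mask_to_intervals(mask)
        for x, y in zip(runs, runs[1:]):
            if y.start - x.end <= gap:
                mask[x.end : y.start] = True
    return mask_to_intervals(mask)


def random_interval_set(rng, chrom_len, n_max=12) -> IntervalSet:
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        s = int(rng.integers(0, chrom_len - 1))
        e = int(rng.integers(s + 1, min(chrom_len, s + 1 + rng.integers(1, 800)) + 1))
        out.append(GenomicInterval("chr1", s, min(e, chrom_len)))
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# literal per-base enhancer-rule evaluation
# ---------------------------------------------------------------------------


def literal_enhancer_rules(
    mark_masks: dict[tuple[str, str], np.ndarray],
    open_peaks: dict[str, list[GenomicInterval]],
    tss_positions: list[int],
    chrom_len: int,
    tss_halfwidth: int = 5000,
):
    """Apply the poised/active rule text literally on boolean base arrays.

    ``mark_masks[(context, mark)]`` holds the filtered+extended coverage of
    one mark; ``open_peaks[context]`` the filtered open-chromatin elements.
    Returns ``{"poised": [...], "active": [...]}`` of merged intervals.
    """
    contexts = sorted(open_peaks)
    tssmask = np.zeros(chrom_len, dtype=bool)
    for t in tss_positions:
        tssmask[max(0, t - tss_halfwidth) : t + tss_halfwidth + 1] = True

    def call(require, forbid):
        candidates = []
        for c in contexts:
            both = mark_masks[(c, require)] & mark_masks[(c, "H3K4me1")]
            for pk in open_peaks[c]:
                if both[pk.start : pk.end].any():
                    candidates.append(pk)
        forbid_mask = np.zeros(chrom_len, dtype=bool)
        for c in contexts:
            forbid_mask |= mark_masks[(c, forbid)]
        kept = [
            pk
            for pk in candidates
            if not tssmask[pk.start : pk.end].any()
            and not forbid_mask[pk.start : pk.end].any()
        ]
        return naive_merge(kept, chrom_len)

    return {
        "poised": call("H3K27me3", "H3K27ac"),
        "active": call("H3K27ac", "H3K27me3"),
    }


# ---------------------------------------------------------------------------
# per-base chain walking
# ---------------------------------------------------------------------------


def chain_walk_ratio(q: GenomicInterval, chain) -> float:
    """Fraction of query bases inside aligned blocks of one chain."""
    aligned = np.zeros(len(q), dtype=bool)
    for t0, t1, _, _ in chain.aligned_blocks():
        lo, hi = max(t0, q.start), min(t1, q.end)
        if lo < hi:
            aligned[lo - q.start : hi - q.start] = True
    return float(aligned.mean())


def chain_walk_targets(q: GenomicInterval, chain) -> list[int]:
    """Forward-strand target position of every aligned query base."""
    out = []
    for t0, t1, q0, _ in chain.aligned_blocks():
        lo, hi = max(t0, q.start), min(t1, q.end)
        for pos in range(lo, hi):
            tgt = q0 + (pos - t0)
            if chain.q_strand == "-":
                tgt = chain.q_size - 1 - tgt
            out.append(tgt)
    return out


# ---------------------------------------------------------------------------
# exact statistics by enumeration
# ---------------------------------------------------------------------------


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of every
    table with the observed margins whose probability is <= the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def ranksum_enumeration(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments
    of the pooled (tie-free) sample."""
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(ranks[pooled[i]] for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return float(min(1.0, p))
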