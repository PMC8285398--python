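"""Cross-species conservation scoring through pairwise alignment chains.

A UCSC chain describes a gapped alignment between a *source* genome (the
``t`` fields of the header, the genome intervals are lifted from) and a
*target* genome (the ``q`` fields). An interval's **mapped ratio** is the
fraction of its bases falling inside aligned blocks of the single
highest-scoring chain overlapping it — the liftOver ``-minMatch`` semantic.
Sequence-level percent identity is not computed; chain coverage is the only
conservation signal, compared inclusively against the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .intervals import GenomicInterval, IntervalSet


@dataclass
class Chain:
    """One alignment chain: header fields plus aligned-block triples."""

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    # per block: (size, dt, dq); dt/dq of the final block are 0
    blocks: list[tuple[int, int, int]]

    def __post_init__(self):
        t_span = sum(s + dt for s, dt, _ in self.blocks)
        q_span = sum(s + dq for s, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.chain_id}: block source span {t_span} != header "
                f"span {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise FormatError(
                f"chain {self.chain_id}: block target span {q_span} != header "
                f"span {self.q_end - self.q_start}"
            )

    def aligned_blocks(self):
        """Yield ``(t_lo, t_hi, q_lo, q_hi)`` per aligned block.

        Coordinates are on the chain's own strands (the target coordinates
        of a ``-`` strand chain index the reversed target sequence).
        """
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            yield t, t + size, q, q + size
            t += size + dt
            q += size + dq


class ChainSet:
    """Chains indexed by source chromosome."""

    def __init__(self, chains: Sequence[Chain] = ()):
        self.chains = list(chains)
        self._by_source: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_source.setdefault(c.t_name, []).append(c)

    def __len__(self):
        return len(self.chains)

    def overlapping(self, iv: GenomicInterval) -> list[Chain]:
        return [
            c
            for c in self._by_source.get(iv.chrom, [])
            if c.t_start < iv.end and iv.start < c.t_end
        ]


def read_chain(path) -> ChainSet:
    """Parse a UCSC chain file (blank-line separated chain stanzas)."""
    chains: list[Chain] = []
    header = None
    blocks: list[tuple[int, int, int]] = []

    def flush():
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise FormatError(
                f"chain {header[11]}: final block line must be a bare size"
            )
        chains.append(
            Chain(
                score=float(header[0]),
                t_name=header[1],
                t_size=int(header[2]),
                t_start=int(header[4]),
                t_end=int(header[5]),
                q_name=header[6],
                q_size=int(header[7]),
                q_strand=header[8],
                q_start=int(header[9]),
                q_end=int(header[10]),
                chain_id=header[11] if len(header) > 11 else str(len(chains)),
                blocks=blocks,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush()
                continue
            if line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "chain":
                flush()
                if len(fields) < 12:
                    raise FormatError(f"{path}:{lineno}: short chain header")
                header = fields[1:]
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: block outside a chain")
                if len(fields) == 1:
                    blocks.append((int(fields[0]), 0, 0))
                elif len(fields) == 3:
                    blocks.append((int(fields[0]), int(fields[1]), int(fields[2])))
                else:
                    raise FormatError(f"{path}:{lineno}: malformed block line")
    flush()
    return ChainSet(chains)


def write_chain(path, chains: ChainSet) -> None:
    with open(path, "w") as fh:
        for c in chains.chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write("\n")


@dataclass
class MappingResult:
    query: GenomicInterval
    mapped_ratio: float
    target_interval: GenomicInterval | None
    chain_id: str | None


def map_interval(
    q: GenomicInterval, chains: ChainSet, max_expansion: float = 10.0
) -> MappingResult:
    """Map one interval through the highest-scoring overlapping chain.

    ``mapped_ratio`` is (aligned query bases)/|q|. The target interval is
    the bounding span of the mapped bases on the target's forward strand
    (``-`` strand chains are reflected); targets expanding beyond
    ``max_expansion`` times the query length are rejected as pathological
    and reported as missing.
    """
    cands = chains.overlapping(q)
    if not cands:
        return MappingResult(q, 0.0, None, None)
    chain = max(cands, key=lambda c: c.score)
    covered = 0
    q_lo, q_hi = None, None  # target span on the chain's target strand
    for t0, t1, qq0, qq1 in chain.aligned_blocks():
        lo, hi = max(t0, q.start), min(t1, q.end)
        if lo >= hi:
            continue
        covered += hi - lo
        tgt_lo = qq0 + (lo - t0)
        tgt_hi = qq0 + (hi - t0)
        q_lo = tgt_lo if q_lo is None else min(q_lo, tgt_lo)
        q_hi = tgt_hi if q_hi is None else max(q_hi, tgt_hi)
    ratio = covered / len(q)
    if covered == 0:
        return MappingResult(q, 0.0, None, chain.chain_id)
    if chain.q_strand == "-":
        q_lo, q_hi = chain.q_size - q_hi, chain.q_size - q_lo
    target = GenomicInterval(chain.q_name, q_lo, q_hi)
    if len(target) > max_expansion * len(q):
        return MappingResult(q, ratio, None, chain.chain_id)
    return MappingResult(q, ratio, target, chain.chain_id)


def conservation_fraction(
    regions: IntervalSet, chains: ChainSet, min_ratio: float
) -> tuple[float | None, pd.DataFrame]:
    """Fraction of elements with mapped_ratio >= min_ratio (inclusive).

    Returns ``(fraction, per-element table)`` with columns chrom/start/end/
    mapped_ratio/conserved/target columns for downstream subsetting.
    """
    if not (0.0 < min_ratio <= 1.0):
        raise ValidationError("min_ratio must be in (0, 1]")
    rows = []
    for iv in regions:
        r = map_interval(iv, chains)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name,
                "mapped_ratio": r.mapped_ratio,
                "conserved": r.mapped_ratio >= min_ratio,
                "target_chrom": r.target_interval.chrom if r.target_interval else None,
                "target_start": r.target_interval.start if r.target_interval else None,
                "target_end": r.target_interval.end if r.target_interval else None,
                "chain_id": r.chain_id,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "mapped_ratio", "conserved",
            "target_chrom", "target_start", "target_end", "chain_id",
        ],
    )
    if len(regions) == 0:
        warnings.warn("conservation_fraction of an empty set is undefined")
        return None, table
    return float(table["conserved"].mean()), table


def threshold_sweep(
    regions: IntervalSet, chains: ChainSet, ratios: Sequence[float]
) -> pd.DataFrame:
    """Conservation fraction at each threshold of a strictly increasing sweep."""
    ratios = list(ratios)
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValidationError("ratios must be strictly increasing")
    if any(not (0.0 < r <= 1.0) for r in ratios):
        raise ValidationError("ratios must be in (0, 1]")
    # one mapping pass; thresholds applied to the cached ratios
    mapped = np.array([map_interval(iv, chains).mapped_ratio for iv in regions])
    rows = []
    for r in ratios:
        frac = float((mapped >= r).mean()) if len(mapped) else None
        rows.append({"min_ratio": r, "fraction_conserved": frac})
    return pd.DataFrame(rows, columns=["min_ratio", "fraction_conserved"])
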