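"""Readers and writers for the plain-text genomic formats the pipeline touches.

All formats are tab-delimited, header-less unless a line starts with
``track``, ``browser`` or ``#`` (skipped). BED intervals are 0-based
half-open on disk and in memory, so reading and writing round-trips
bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

from .errors import FormatError, ValidationError
from .intervals import Genome, GenomicInterval, IntervalSet, SignalTrack, TssRecord

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


@dataclass(frozen=True)
class PeakRecord:
    """One peak-caller record with its enrichment and significance columns."""

    interval: GenomicInterval
    fold_enrichment: float
    p_value: float | None
    q_value: float | None
    summit_offset: int | None = None

    def __post_init__(self):
        if self.fold_enrichment < 0:
            raise ValidationError("fold_enrichment must be >= 0")
        for v in (self.p_value, self.q_value):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"probability {v} outside [0,1]")


def read_bed(path, genome: Genome | None = None) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet (order preserved)."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand, name))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(out, genome)


def write_bed(path, ivs: IntervalSet, scores: Sequence | None = None) -> None:
    """Write BED3 (or BED6 when any interval carries a name/strand)."""
    six = any(iv.name is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if six:
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> Genome:
    """Two-column ``chrom<TAB>length`` file."""
    genome: Genome = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        genome[fields[0]] = int(fields[1])
    return genome


def write_chrom_sizes(path, genome: Genome) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.items():
            fh.write(f"{chrom}\t{size}\n")


_DIALECT_COLUMNS = {"narrowPeak": 10, "broadPeak": 9}


def _from_neglog10(field: str) -> float | None:
    """ENCODE encodes missing p/q as -1; stored values are -log10."""
    x = float(field)
    if x < 0:
        return None
    return float(10.0 ** (-x))


def read_peaks(path, dialect: str) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (10 col) or broadPeak (9 col) file.

    ``signalValue`` (column 7) is the fold enrichment over input; columns 8
    and 9 hold -log10 p and -log10 q and are converted back to
    probabilities, with the ENCODE ``-1`` sentinel mapped to missing.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValidationError(f"unknown peak dialect {dialect!r}")
    want = _DIALECT_COLUMNS[dialect]
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) != want:
            raise FormatError(
                f"{path}:{lineno}: {dialect} requires {want} columns, "
                f"got {len(fields)}"
            )
        iv = GenomicInterval(
            fields[0],
            int(fields[1]),
            int(fields[2]),
            fields[5] if fields[5] in "+-" else ".",
            fields[3] if fields[3] != "." else None,
        )
        summit = None
        if dialect == "narrowPeak":
            summit = int(fields[9])
            if summit < 0:
                summit = None
        out.append(
            PeakRecord(
                interval=iv,
                fold_enrichment=float(fields[6]),
                p_value=_from_neglog10(fields[7]),
                q_value=_from_neglog10(fields[8]),
                summit_offset=summit,
            )
        )
    return out


def _to_neglog10(p: float | None) -> str:
    import math

    if p is None:
        return "-1"
    if p <= 0:
        return "400"  # macs2-style cap for underflowed probabilities
    return f"{-math.log10(p):.5f}"


def write_peaks(path, peaks: Sequence[PeakRecord], dialect: str) -> None:
    if dialect not in _DIALECT_COLUMNS:
        raise ValidationError(f"unknown peak dialect {dialect!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            row = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name or f"peak_{i + 1}",
                "0",
                iv.strand if iv.strand in "+-" else ".",
                f"{p.fold_enrichment:.5f}",
                _to_neglog10(p.p_value),
                _to_neglog10(p.q_value),
            ]
            if dialect == "narrowPeak":
                row.append(str(p.summit_offset if p.summit_offset is not None else -1))
            fh.write("\t".join(row) + "\n")


def peaks_to_intervals(
    peaks: Sequence[PeakRecord], genome: Genome | None = None
) -> IntervalSet:
    return IntervalSet([p.interval for p in peaks], genome)


def read_bedgraph(path) -> SignalTrack:
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph requires 4 columns")
        records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return SignalTrack.from_records(records)


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.data:
            starts, ends, vals = track.data[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_tss(path) -> list[TssRecord]:
    """Read a BED6 TSS annotation: name column = gene id, start = TSS base.

    For ``-`` strand rows wider than one base the TSS is taken at ``end-1``.
    Gene ids must be unique.
    """
    out: list[TssRecord] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: TSS BED requires >=4 columns")
        gene = fields[3]
        if gene in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        start, end = int(fields[1]), int(fields[2])
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        pos = end - 1 if (strand == "-" and end - start > 1) else start
        out.append(TssRecord(gene_id=gene, chrom=fields[0], position=pos, strand=strand))
    return out


def write_tss(path, tss: Sequence[TssRecord]) -> None:
    with open(path, "w") as fh:
        for t in tss:
            fh.write(
                f"{t.chrom}\t{t.position}\t{t.position + 1}\t{t.gene_id}\t0\t"
                f"{t.strand if t.strand in '+-' else '.'}\n"
            )


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
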