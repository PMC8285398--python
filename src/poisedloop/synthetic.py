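"""Synthetic epigenome generator with machine-readable planted truth.

Emulates, at desk scale, the data the pipeline consumes: a toy two-genome
pair, TSS/CGI/TAD/PcG annotations, multi-context peak libraries over
planted enhancer classes, an alignment chain with prescribed per-element
mapped ratios, significance-annotated loop lists, and distance-decaying
contact matrices with planted center enrichments.

Planted elements live on a coarse slot grid (one element per slot, slots
tens of kilobases apart) so that no two planted features interact through
peak extension, TSS windows, or merging: every downstream call is then
exactly predictable from the truth manifest. Noise peaks are placed on a
finer grid kept clear of planted slots, and no two noise peaks overlap, so
noise can never assemble the multi-mark signature of an enhancer class.

Determinism: every random draw comes from one ``numpy`` generator seeded
from ``SimConfig.seed``; the emitted files are byte-identical across runs
with the same configuration.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
import numpy as np

from .conservation import Chain, ChainSet, write_chain
from .contacts import ContactMatrix, write_coo
from .enhancers import LaterAcSet, MarkLibrary
from .errors import GenerationError
from .intervals import Genome, GenomicInterval, IntervalSet, TssRecord
from .io import (
    PeakRecord,
    write_bed,
    write_chrom_sizes,
    write_peaks,
    write_tss,
)
from .loops import Loop, LoopSet, write_bedpe

ENHANCER_CLASSES = ("poised", "active", "primed", "poiact")

# mark signature per class, shared by every context
CLASS_SIGNATURE = {
    "poised": ("ATAC", "H3K4me1", "H3K27me3"),
    "poiact": ("ATAC", "H3K4me1", "H3K27me3"),
    "active": ("ATAC", "H3K4me1", "H3K27ac"),
    "primed": ("H3K4me1",),
}

# fold-enrichment thresholds the downstream rules apply (study defaults)
MARK_MIN_FOLD = {"ATAC": 4.0, "H3K4me1": 2.0, "H3K27me3": 2.0, "H3K27ac": 5.0}
MARK_DIALECT = {
    "ATAC": "narrowPeak",
    "H3K4me1": "broadPeak",
    "H3K27me3": "broadPeak",
    "H3K27ac": "broadPeak",
}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions at desk scale."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 6_000_000}
    )
    contexts: tuple[str, ...] = ("naive", "serum", "formative")
    n_poised: int = 60
    n_active: int = 60
    n_primed: int = 50
    n_poiact: int = 30
    n_tss: int = 40
    n_background_cgi: int = 20
    n_pcg_domains: int = 12
    element_slot_spacing: int = 30_000
    element_widths: tuple[int, ...] = (800, 1000, 1200, 1600, 2000)
    cgi_proximity_fraction: float = 0.75  # share of poised elements within 3 kb of a CGI
    cgi_distance: int = 1000
    cgi_width: int = 400
    noise_rate_per_mb: float = 5.0  # false peaks per Mb per (context, mark)
    # conservation: prescribed mapped ratios cycled over planted elements
    conserved_ratio_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    # TADs tile each chromosome with gaps
    tad_size: int = 400_000
    tad_gap: int = 50_000
    # loops
    n_loops_pe_promoter: int = 30
    n_loops_pe_pe: int = 15
    n_loops_pe_pcg: int = 15
    n_loops_pe_other: int = 20
    n_loops_background: int = 40
    loop_anchor_halfwidth: int = 2_500
    # contacts
    contact_resolution: int = 5_000
    contact_bins: int = 500
    contact_decay_alpha: float = 1.0
    contact_diag_intensity: float = 2_000.0
    loop_enrichment: float = 5.0
    n_contact_pairs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.contact_decay_alpha <= 0:
            raise GenerationError("decay exponent must be > 0")
        if self.noise_rate_per_mb < 0 or self.cgi_proximity_fraction < 0:
            raise GenerationError("rates must be >= 0")

    @property
    def n_elements(self) -> int:
        return self.n_poised + self.n_active + self.n_primed + self.n_poiact


@dataclass
class PlantedElement:
    chrom: str
    start: int
    end: int
    enhancer_class: str
    conserved_ratio: float
    near_cgi: bool

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.enhancer_class)


@dataclass
class Annotation:
    genome: Genome
    tss: list[TssRecord]
    promoter_states: dict[str, str]
    cgis: IntervalSet
    tads: IntervalSet
    pcg_domains: IntervalSet
    elements: list[PlantedElement]

    def elements_of(self, cls: str) -> IntervalSet:
        return IntervalSet(
            [e.interval for e in self.elements if e.enhancer_class == cls],
            self.genome,
        )


def _slot_grid(cfg: SimConfig, spacing: int, margin: int) -> list[tuple[str, int]]:
    slots = []
    for chrom, length in cfg.chrom_lengths.items():
        pos = margin
        while pos < length - margin:
            slots.append((chrom, pos))
            pos += spacing
    return slots


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None) -> Annotation:
    """Place TSS, planted enhancer elements, CGIs, TADs and PcG domains.

    A configurable fraction of planted poised/poiact elements gets a CGI
    within 3 kb, emulating the strong CGI proximity of poised enhancers.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    slots = _slot_grid(cfg, cfg.element_slot_spacing, margin=25_000)
    need = cfg.n_tss + cfg.n_elements + cfg.n_background_cgi + cfg.n_pcg_domains
    if need > len(slots):
        raise GenerationError(
            f"need {need} slots but the genome provides {len(slots)}; "
            "enlarge chromosomes or reduce counts"
        )
    order = rng.permutation(len(slots))
    cursor = 0

    def take(n):
        nonlocal cursor
        chosen = [slots[i] for i in order[cursor : cursor + n]]
        cursor += n
        return chosen

    tss_slots = take(cfg.n_tss)
    element_slots = take(cfg.n_elements)
    cgi_slots = take(cfg.n_background_cgi)
    pcg_slots = take(cfg.n_pcg_domains)

    tss = [
        TssRecord(gene_id=f"gene{i:03d}", chrom=c, position=p,
                  strand="+" if i % 2 == 0 else "-")
        for i, (c, p) in enumerate(tss_slots)
    ]
    states = [
        ("bivalent", "k27me3_only", "k4me3_only", "unmarked")[i % 4]
        for i in range(cfg.n_tss)
    ]
    state_order = rng.permutation(cfg.n_tss)
    promoter_states = {tss[i].gene_id: states[j] for j, i in enumerate(state_order)}

    labels = (
        ["poised"] * cfg.n_poised
        + ["active"] * cfg.n_active
        + ["primed"] * cfg.n_primed
        + ["poiact"] * cfg.n_poiact
    )
    ratios = [
        cfg.conserved_ratio_levels[i % len(cfg.conserved_ratio_levels)]
        for i in range(cfg.n_elements)
    ]
    elements: list[PlantedElement] = []
    cgi_intervals: list[GenomicInterval] = []
    pe_seen = 0
    for i, ((chrom, center), label) in enumerate(zip(element_slots, labels)):
        width = int(rng.choice(cfg.element_widths))
        start = center - width // 2
        near = False
        if label in ("poised", "poiact"):
            # deterministic fraction: the first ceil(f * n) poised-like
            # elements get a nearby CGI
            near = pe_seen < round(
                cfg.cgi_proximity_fraction * (cfg.n_poised + cfg.n_poiact)
            )
            pe_seen += 1
        elements.append(
            PlantedElement(chrom, start, start + width, label, ratios[i], near)
        )
        if near:
            cgi_start = start + width + cfg.cgi_distance
            cgi_intervals.append(
                GenomicInterval(chrom, cgi_start, cgi_start + cfg.cgi_width)
            )
    for chrom, center in cgi_slots:
        cgi_intervals.append(
            GenomicInterval(chrom, center - cfg.cgi_width // 2,
                            center + cfg.cgi_width // 2)
        )

    tads = []
    for chrom, length in cfg.chrom_lengths.items():
        pos = 0
        while pos + cfg.tad_size <= length:
            tads.append(GenomicInterval(chrom, pos, pos + cfg.tad_size))
            pos += cfg.tad_size + cfg.tad_gap

    pcg = [
        GenomicInterval(c, p - 1_500, p + 1_500) for c, p in pcg_slots
    ]
    genome = dict(cfg.chrom_lengths)
    return Annotation(
        genome=genome,
        tss=tss,
        promoter_states=promoter_states,
        cgis=IntervalSet(sorted(cgi_intervals, key=GenomicInterval.sort_key), genome),
        tads=IntervalSet(tads, genome),
        pcg_domains=IntervalSet(pcg, genome),
        elements=elements,
    )


def _planted_fold(rng, mark) -> float:
    thr = MARK_MIN_FOLD[mark]
    return float(thr * rng.uniform(1.5, 4.0))


def _noise_fold(rng, mark) -> float:
    thr = MARK_MIN_FOLD[mark]
    return float(thr * rng.uniform(0.5, 1.5))


def _peak(iv: GenomicInterval, fold: float, q: float, dialect: str) -> PeakRecord:
    return PeakRecord(
        interval=iv,
        fold_enrichment=fold,
        p_value=min(1.0, q / 2),
        q_value=q,
        summit_offset=len(iv) // 2 if dialect == "narrowPeak" else None,
    )


@dataclass
class PeakLibraryBundle:
    marks: MarkLibrary
    later_sets: list[LaterAcSet]
    promoter_k4me3: IntervalSet
    promoter_k27me3: IntervalSet
    n_noise_peaks: int


def simulate_peak_library(
    cfg: SimConfig, ann: Annotation, rng: np.random.Generator | None = None
) -> PeakLibraryBundle:
    """Emit per-context peak sets realising each planted element's signature.

    Planted peaks draw fold enrichments comfortably above the class
    thresholds and strongly significant q values; noise peaks straddle the
    thresholds (roughly half survive filtering) and are placed so that they
    never overlap planted elements or each other. Promoter-state marks
    (H3K4me3/H3K27me3 at TSS) are returned as separate sets so promoter
    chromatin classification has its own planted truth.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    lib = MarkLibrary(genome=ann.genome)
    marks = ("ATAC", "H3K4me1", "H3K27me3", "H3K27ac")

    peaks: dict[tuple[str, str], list[PeakRecord]] = {
        (c, m): [] for c in cfg.contexts for m in marks
    }
    later_peaks: list[PeakRecord] = []
    for el in ann.elements:
        iv = GenomicInterval(el.chrom, el.start, el.end)
        for context in cfg.contexts:
            for mark in CLASS_SIGNATURE[el.enhancer_class]:
                q = float(10.0 ** -rng.uniform(3.0, 8.0))
                peaks[(context, mark)].append(
                    _peak(iv, _planted_fold(rng, mark), q, MARK_DIALECT[mark])
                )
        if el.enhancer_class == "poiact":
            q = float(10.0 ** -rng.uniform(3.0, 8.0))
            later_peaks.append(
                _peak(iv, _planted_fold(rng, "H3K27ac"), q, "broadPeak")
            )

    # noise: a fine slot grid kept >= 10 kb away from planted slots
    n_noise = 0
    if cfg.noise_rate_per_mb > 0:
        genome_mb = sum(cfg.chrom_lengths.values()) / 1e6
        per_track = int(round(cfg.noise_rate_per_mb * genome_mb))
        fine = _slot_grid(cfg, spacing=8_000, margin=25_000)
        planted_pos = {
            (e.chrom, (e.start + e.end) // 2 // cfg.element_slot_spacing)
            for e in ann.elements
        }
        keep = []
        anchors = [(e.chrom, (e.start + e.end) // 2) for e in ann.elements]
        anchors += [(t.chrom, t.position) for t in ann.tss]
        anchors += [(iv.chrom, iv.midpoint) for iv in ann.cgis]
        anchors += [(iv.chrom, iv.midpoint) for iv in ann.pcg_domains]
        by_chrom: dict[str, np.ndarray] = {}
        for chrom in cfg.chrom_lengths:
            pos = np.array(sorted(p for c, p in anchors if c == chrom))
            by_chrom[chrom] = pos
        for chrom, p in fine:
            pos = by_chrom[chrom]
            i = np.searchsorted(pos, p)
            near = min(
                abs(p - pos[j]) for j in (i - 1, i) if 0 <= j < len(pos)
            ) if len(pos) else np.inf
            if near > 10_000:
                keep.append((chrom, p))
        tracks = [(c, m) for c in cfg.contexts for m in marks]
        need = per_track * len(tracks)
        if need > len(keep):
            raise GenerationError(
                f"noise rate needs {need} clear slots, only {len(keep)} exist"
            )
        order = rng.permutation(len(keep))
        cursor = 0
        for c, m in tracks:
            for _ in range(per_track):
                chrom, center = keep[order[cursor]]
                cursor += 1
                width = int(rng.choice(cfg.element_widths))
                iv = GenomicInterval(chrom, center - width // 2, center + width // 2)
                q = float(10.0 ** -rng.uniform(0.5, 3.0))
                peaks[(c, m)].append(
                    _peak(iv, _noise_fold(rng, m), q, MARK_DIALECT[m])
                )
                n_noise += 1

    for (c, m), plist in peaks.items():
        plist.sort(key=lambda p: p.interval.sort_key())
        lib.add(c, m, plist)
    later_peaks.sort(key=lambda p: p.interval.sort_key())
    later = [LaterAcSet(replicates=[later_peaks], label="later_k27ac")]

    k4me3, k27me3 = [], []
    for t in ann.tss:
        state = ann.promoter_states[t.gene_id]
        win = GenomicInterval(t.chrom, max(0, t.position - 500), t.position + 500)
        if state in ("bivalent", "k4me3_only"):
            k4me3.append(win)
        if state in ("bivalent", "k27me3_only"):
            k27me3.append(win)
    return PeakLibraryBundle(
        marks=lib,
        later_sets=later,
        promoter_k4me3=IntervalSet(k4me3, ann.genome),
        promoter_k27me3=IntervalSet(k27me3, ann.genome),
        n_noise_peaks=n_noise,
    )


def simulate_chain(cfg: SimConfig, ann: Annotation) -> ChainSet:
    """One chain per chromosome realising each element's prescribed ratio.

    Within a planted element of length L and ratio r, exactly ``r * L``
    leading bases are aligned (an error is raised if ``r * L`` is not a
    whole number of bases); everything between elements is aligned, so the
    element's mapped ratio is exact by construction.
    """
    chains = []
    for ci, (chrom, length) in enumerate(cfg.chrom_lengths.items()):
        els = sorted(
            (e for e in ann.elements if e.chrom == chrom), key=lambda e: e.start
        )
        # segments: (t_aligned_len, t_gap_len) alternating from position 0
        blocks: list[tuple[int, int, int]] = []  # (size, dt, dq)
        pending_aligned = 0
        pos = 0
        for e in els:
            L = e.end - e.start
            aligned = e.conserved_ratio * L
            if abs(aligned - round(aligned)) > 1e-9:
                raise GenerationError(
                    f"ratio {e.conserved_ratio} unreachable on a {L} bp element"
                )
            aligned = int(round(aligned))
            gap = L - aligned
            pending_aligned += (e.start - pos) + aligned
            if gap > 0:
                blocks.append((pending_aligned, gap, 0))
                pending_aligned = 0
            pos = e.end
        pending_aligned += length - pos
        blocks.append((pending_aligned, 0, 0))
        q_len = sum(b[0] for b in blocks)
        chains.append(
            Chain(
                score=1000.0,
                t_name=chrom,
                t_size=length,
                t_start=0,
                t_end=length,
                q_name=f"b_{chrom}",
                q_size=q_len,
                q_strand="+",
                q_start=0,
                q_end=q_len,
                chain_id=str(ci + 1),
                blocks=blocks,
            )
        )
    return ChainSet(chains)


def _tad_index(ann: Annotation, chrom: str, pos: int) -> int | None:
    for i, iv in enumerate(ann.tads):
        if iv.chrom == chrom and iv.start <= pos < iv.end:
            return i
    return None


@dataclass
class LoopTruth:
    category: str  # promoter | seed | pcg_domain | other | background
    tad_status: str  # intra | inter | unassigned
    significant: bool


def simulate_loops(
    cfg: SimConfig, ann: Annotation, rng: np.random.Generator | None = None
) -> tuple[LoopSet, list[LoopTruth]]:
    """Plant loops of known partner category, TAD status and significance.

    Anchors are ``2 * loop_anchor_halfwidth`` wide, centred on planted
    features; the partner-category truth follows from construction (slots
    never sit inside another feature's annotation window) and the TAD
    status is recorded from a direct scan of the TAD tiling.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    hw = cfg.loop_anchor_halfwidth
    pes = [e for e in ann.elements if e.enhancer_class in ("poised", "poiact")]
    free_slots = [
        (c, p)
        for c, p in _slot_grid(cfg, cfg.element_slot_spacing, margin=25_000)
        if _is_free_slot(ann, c, p)
    ]

    def anchor(chrom, center):
        return GenomicInterval(chrom, max(0, center - hw), center + hw)

    def pe_center(e: PlantedElement):
        return e.chrom, (e.start + e.end) // 2

    def pick(seq):
        return seq[int(rng.integers(len(seq)))]

    plan: list[tuple[str, tuple[str, int], tuple[str, int]]] = []
    for _ in range(cfg.n_loops_pe_promoter):
        e = pick(pes)
        cands = [t for t in ann.tss if t.chrom == e.chrom]
        if cands:
            plan.append(("promoter", pe_center(e), (e.chrom, pick(cands).position)))
    for _ in range(cfg.n_loops_pe_pe):
        e1 = pick(pes)
        cands = [e for e in pes if e.chrom == e1.chrom and e is not e1]
        if cands:
            plan.append(("seed", pe_center(e1), pe_center(pick(cands))))
    for _ in range(cfg.n_loops_pe_pcg):
        e = pick(pes)
        cands = [p for p in ann.pcg_domains if p.chrom == e.chrom]
        if cands:
            plan.append(("pcg_domain", pe_center(e), (e.chrom, pick(cands).midpoint)))
    for _ in range(cfg.n_loops_pe_other):
        e = pick(pes)
        cands = [s for s in free_slots if s[0] == e.chrom]
        if cands:
            plan.append(("other", pe_center(e), pick(cands)))
    for _ in range(cfg.n_loops_background):
        s1 = pick(free_slots)
        cands = [s for s in free_slots if s[0] == s1[0] and s != s1]
        if cands:
            plan.append(("background", s1, pick(cands)))

    loops, truths = [], []
    for category, (c1, p1), (c2, p2) in plan:
        if abs(p1 - p2) < 4 * hw:  # too close to form ordered disjoint anchors
            continue
        if p2 < p1:
            (c1, p1), (c2, p2) = (c2, p2), (c1, p1)
        a1, a2 = anchor(c1, p1), anchor(c2, p2)
        significant = category != "background" or rng.uniform() < 0.25
        if significant:
            p = float(10.0 ** -rng.uniform(2.05, 6.0))  # < 0.01
            q = float(10.0 ** -rng.uniform(1.05, 5.0))  # < 0.1
            pet = int(rng.poisson(20) + 5)
        else:
            p = float(rng.uniform(0.2, 0.8))
            q = float(rng.uniform(0.2, 0.8))
            pet = int(rng.poisson(4) + 1)
        loops.append(Loop(a1, a2, p_value=p, q_value=q, pet_count=pet))
        t1 = _tad_index(ann, c1, a1.midpoint)
        t2 = _tad_index(ann, c2, a2.midpoint)
        status = (
            "unassigned" if (t1 is None or t2 is None)
            else "intra" if t1 == t2
            else "inter"
        )
        truths.append(LoopTruth(category, status, significant))
    return LoopSet(loops, ann.genome), truths


def _is_free_slot(ann: Annotation, chrom: str, pos: int) -> bool:
    """True when no planted feature sits within 12 kb of the slot center."""
    for e in ann.elements:
        if e.chrom == chrom and abs((e.start + e.end) // 2 - pos) < 12_000:
            return False
    for t in ann.tss:
        if t.chrom == chrom and abs(t.position - pos) < 12_000:
            return False
    for iv in list(ann.pcg_domains) + list(ann.cgis):
        if iv.chrom == chrom and abs(iv.midpoint - pos) < 12_000:
            return False
    return True


@dataclass
class ContactTruth:
    pairs: list[tuple[GenomicInterval, GenomicInterval]]
    enrichment: float
    decay_alpha: float


def simulate_contacts(
    cfg: SimConfig,
    enrichment: float | None = None,
    n_pairs: int | None = None,
    rng: np.random.Generator | None = None,
    chrom: str = "chrC",
) -> tuple[ContactMatrix, ContactTruth]:
    """A distance-decaying Poisson contact matrix with planted loop pixels.

    Expected counts at bin separation d are
    ``diag_intensity * (1 + d) ** -alpha``; the pixel at each planted pair's
    center is multiplied by the enrichment factor before Poisson sampling.
    ``enrichment=1`` gives the loop-free null.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    k = cfg.loop_enrichment if enrichment is None else enrichment
    n_pairs = cfg.n_contact_pairs if n_pairs is None else n_pairs
    n = cfg.contact_bins
    res = cfg.contact_resolution
    w = 250_000 // res  # default pileup halfwidth in bins

    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = cfg.contact_diag_intensity * (1.0 + d) ** (-cfg.contact_decay_alpha)

    pairs = []
    used_pixels: set[tuple[int, int]] = set()
    min_sep, max_sep = 2 * w + 20, n - 2 * w - 22
    for _ in range(n_pairs):
        while True:
            sep = int(rng.integers(min_sep, max_sep + 1))
            bi = int(rng.integers(w, n - w - sep))
            bj = bi + sep
            if (bi, bj) not in used_pixels:
                used_pixels.add((bi, bj))
                break
        lam[bi, bj] *= k
        lam[bj, bi] = lam[bi, bj]
        mid_i = bi * res + res // 2
        mid_j = bj * res + res // 2
        pairs.append(
            (
                GenomicInterval(chrom, mid_i - 500, mid_i + 500),
                GenomicInterval(chrom, mid_j - 500, mid_j + 500),
            )
        )
    upper = np.triu(rng.poisson(lam)).astype(float)
    counts = upper + np.triu(upper, 1).T
    cm = ContactMatrix(chrom, res, counts)
    return cm, ContactTruth(pairs=pairs, enrichment=k, decay_alpha=cfg.contact_decay_alpha)


# ---------------------------------------------------------------------------
# Bundled simulation + file emission + truth manifest
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    config: SimConfig
    annotation: Annotation
    peaks: PeakLibraryBundle
    chains: ChainSet
    loops: LoopSet
    loop_truth: list[LoopTruth]
    contacts: ContactMatrix
    contact_truth: ContactTruth


def simulate_all(cfg: SimConfig) -> SimResult:
    """Run every generator stage off one seeded random stream family."""
    ann = simulate_annotation(cfg)
    peaks = simulate_peak_library(cfg, ann)
    chains = simulate_chain(cfg, ann)
    loops, loop_truth = simulate_loops(cfg, ann)
    contacts, contact_truth = simulate_contacts(cfg)
    return SimResult(cfg, ann, peaks, chains, loops, loop_truth, contacts, contact_truth)


def truth_manifest(sim: SimResult) -> dict:
    """Machine-readable planted truth sufficient to predict every stage."""
    cfg = sim.config
    return {
        "generator": {"seed": cfg.seed, "config": asdict(cfg)},
        "elements": [asdict(e) for e in sim.annotation.elements],
        "promoter_states": sim.annotation.promoter_states,
        "conserved_fraction_at": {
            f"{thr:.2f}": float(
                np.mean([e.conserved_ratio >= thr for e in sim.annotation.elements])
            )
            for thr in (0.2, 0.5, 0.8)
        },
        "loops": [asdict(t) for t in sim.loop_truth],
        "contacts": {
            "enrichment": sim.contact_truth.enrichment,
            "decay_alpha": sim.contact_truth.decay_alpha,
            "n_pairs": len(sim.contact_truth.pairs),
        },
        "n_noise_peaks": sim.peaks.n_noise_peaks,
    }


def write_simulation(sim: SimResult, outdir: str) -> dict[str, str]:
    """Write every stage's files (plain text) plus the truth manifest.

    Returns a mapping role -> path for downstream configuration.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_chrom_sizes(p("genome.chrom.sizes"), sim.annotation.genome)
    write_tss(p("tss.bed"), sim.annotation.tss)
    write_bed(p("cgi.bed"), sim.annotation.cgis)
    write_bed(p("tads.bed"), sim.annotation.tads)
    write_bed(p("pcg_domains.bed"), sim.annotation.pcg_domains)
    for (context, mark), plist in sorted(sim.peaks.marks.items()):
        dialect = MARK_DIALECT[mark]
        ext = "narrowPeak" if dialect == "narrowPeak" else "broadPeak"
        write_peaks(p(f"{context}_{mark}.{ext}"), plist, dialect)
    for ls in sim.peaks.later_sets:
        for ri, rep in enumerate(ls.replicates, start=1):
            write_peaks(p(f"{ls.label}_rep{ri}.broadPeak"), rep, "broadPeak")
    write_bed(p("promoter_H3K4me3.bed"), sim.peaks.promoter_k4me3)
    write_bed(p("promoter_H3K27me3.bed"), sim.peaks.promoter_k27me3)
    write_chain(p("toy.chain"), sim.chains)
    write_bedpe(p("loops.bedpe"), sim.loops)
    write_coo(p("contacts.coo.tsv"), sim.contacts)
    write_bedpe(
        p("contact_pairs.bedpe"),
        LoopSet([Loop(a, b) for a, b in sim.contact_truth.pairs]),
    )
    with open(p("truth_manifest.json"), "w") as fh:
        json.dump(truth_manifest(sim), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
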