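"""Config-driven orchestration of the analysis stages.

Each ``stage_*`` function reads its inputs from files (the formats
``synthetic.write_simulation`` emits and the field's standard tools
produce), runs the corresponding library module, writes its outputs under
an output directory, and returns a JSON-serialisable report section. A run
is fully deterministic for a fixed seed: no timestamps or machine state
enter any output file (timing information goes to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    assign_nearest_gene,
    cgi_distance_profile,
    classify_promoter_states,
    enrichment_fisher,
)
from .conservation import read_chain, threshold_sweep
from .contacts import pileup, read_coo
from .enhancers import (
    CallingParams,
    LaterAcSet,
    MarkLibrary,
    call_active_invitro,
    call_poiact,
    call_poised_invitro,
    call_primed_invitro,
    resolve_class_overlaps,
)
from .errors import ConfigurationError
from .intervals import GenomicInterval, IntervalSet
from .io import (
    ensure_dir,
    read_bed,
    read_chrom_sizes,
    read_peaks,
    read_tss,
    write_bed,
)
from .loops import (
    TadSet,
    annotate_partner,
    classify_tad_status,
    default_hierarchy,
    filter_loops,
    interaction_summary,
    loop_size_distribution,
    loopset_overlap,
    read_bedpe,
)
from .synthetic import MARK_DIALECT, SimConfig, simulate_all, write_simulation

logger = logging.getLogger(__name__)

CONSERVATION_RATIOS = (0.2, 0.35, 0.5, 0.65, 0.8, 0.99)


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _dump_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(cfg: SimConfig, outdir: str) -> dict:
    sim = simulate_all(cfg)
    paths = write_simulation(sim, outdir)
    # basenames only, so reruns into different directories stay byte-identical
    _dump_json(
        os.path.join(outdir, "paths.json"),
        {k: os.path.basename(v) for k, v in paths.items()},
    )
    return {
        "stage": "simulate",
        "seed": cfg.seed,
        "n_elements": cfg.n_elements,
        "n_loops": len(sim.loops),
        "outdir": os.path.basename(outdir.rstrip("/")),
    }


def _load_mark_library(paths: dict, contexts: Sequence[str], genome) -> MarkLibrary:
    lib = MarkLibrary(genome=genome)
    for context in contexts:
        for mark, dialect in MARK_DIALECT.items():
            ext = "narrowPeak" if dialect == "narrowPeak" else "broadPeak"
            key = f"{context}_{mark}.{ext}"
            if key in paths:
                lib.add(context, mark, read_peaks(paths[key], dialect))
    return lib


def stage_call_enhancers(
    paths: dict,
    outdir: str,
    contexts: Sequence[str] = ("naive", "serum", "formative"),
    params: CallingParams | None = None,
) -> dict:
    """Call and resolve the four enhancer classes; write BEDs + provenance."""
    ensure_dir(outdir)
    params = params or CallingParams()
    genome = read_chrom_sizes(paths["genome.chrom.sizes"])
    tss = read_tss(paths["tss.bed"])
    lib = _load_mark_library(paths, contexts, genome)
    poised = call_poised_invitro(lib, contexts, tss, params)
    active = call_active_invitro(lib, contexts, tss, params)
    primed = call_primed_invitro(lib, contexts, tss, params)
    resolved = resolve_class_overlaps(poised, active, primed)
    later_key = sorted(k for k in paths if k.startswith("later_k27ac"))
    later = [
        LaterAcSet(replicates=[read_peaks(paths[k], "broadPeak") for k in later_key])
    ] if later_key else []
    poiact, still_poised = call_poiact(resolved["poised"], later, genome)
    classes = {
        "poised": still_poised,
        "active": resolved["active"],
        "primed": resolved["primed"],
        "poiact": poiact,
    }
    prov_rows = []
    for label, calls in classes.items():
        named = IntervalSet(
            [
                GenomicInterval(c.interval.chrom, c.interval.start,
                                c.interval.end, c.interval.strand, label)
                for c in calls
            ],
            genome,
        )
        write_bed(os.path.join(outdir, f"enhancers_{label}.bed"), named)
        for c in calls:
            prov_rows.append(
                {
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "class": label,
                    "provenance": " | ".join(c.provenance),
                }
            )
    pd.DataFrame(
        prov_rows, columns=["chrom", "start", "end", "class", "provenance"]
    ).to_csv(os.path.join(outdir, "enhancer_provenance.tsv"), sep="\t", index=False)
    # all poised-class elements (poised + later-activated) for downstream stages
    pe_all = IntervalSet(
        [c.interval for c in classes["poised"] + classes["poiact"]], genome
    ).sorted()
    write_bed(os.path.join(outdir, "enhancers_pe_all.bed"), pe_all)
    return {
        "stage": "call_enhancers",
        "counts": {k: len(v) for k, v in classes.items()},
    }


def stage_conserve(
    paths: dict,
    outdir: str,
    enhancer_bed: str,
    ratios: Sequence[float] = CONSERVATION_RATIOS,
) -> dict:
    ensure_dir(outdir)
    genome = read_chrom_sizes(paths["genome.chrom.sizes"])
    regions = read_bed(enhancer_bed, genome)
    chains = read_chain(paths["toy.chain"])
    sweep = threshold_sweep(regions, chains, list(ratios))
    sweep.to_csv(os.path.join(outdir, "conservation_sweep.tsv"), sep="\t", index=False)
    fractions = dict(
        zip(
            (f"{r:.2f}" for r in sweep["min_ratio"]),
            (round(float(f), 6) for f in sweep["fraction_conserved"]),
        )
    )
    return {"stage": "conserve", "n_regions": len(regions), "fractions": fractions}


def stage_associate(
    paths: dict,
    outdir: str,
    enhancer_bed: str,
    interacting_genes: Sequence[str] | None = None,
) -> dict:
    """CGI distances, promoter chromatin states, nearest genes, and (when an
    interacting-gene list is supplied) the bivalent-promoter Fisher test."""
    ensure_dir(outdir)
    genome = read_chrom_sizes(paths["genome.chrom.sizes"])
    enhancers = read_bed(enhancer_bed, genome)
    cgis = read_bed(paths["cgi.bed"], genome)
    tss = read_tss(paths["tss.bed"])
    dists, overlap_pct = cgi_distance_profile(enhancers, cgis)
    pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in enhancers],
            "start": [iv.start for iv in enhancers],
            "end": [iv.end for iv in enhancers],
            "cgi_distance": dists,
        }
    ).to_csv(os.path.join(outdir, "cgi_distances.tsv"), sep="\t", index=False)
    k4 = read_bed(paths["promoter_H3K4me3.bed"], genome)
    k27 = read_bed(paths["promoter_H3K27me3.bed"], genome)
    states = classify_promoter_states(tss, k4, k27)
    states.to_csv(os.path.join(outdir, "promoter_states.tsv"), sep="\t", index=False)
    nearest = assign_nearest_gene(enhancers, tss)
    nearest.to_csv(os.path.join(outdir, "nearest_genes.tsv"), sep="\t", index=False)
    report = {
        "stage": "associate",
        "cgi_overlap_pct": overlap_pct,
        "promoter_state_counts": states["state"].value_counts().to_dict(),
    }
    if interacting_genes is not None:
        hit = states["gene_id"].isin(set(interacting_genes)).to_numpy()
        cat = (states["state"] == "bivalent").to_numpy()
        f = enrichment_fisher(hit, cat)
        report["bivalent_fisher"] = {
            "a": f.a, "b": f.b, "c": f.c, "d": f.d,
            "odds_ratio": f.odds_ratio, "p_two_sided": f.p_two_sided,
        }
        _dump_json(os.path.join(outdir, "bivalent_fisher.json"), report["bivalent_fisher"])
    return report


def stage_loops(
    paths: dict,
    outdir: str,
    enhancer_bed: str,
    max_p: float = 0.01,
    anchor_ext: int = 10_000,
    tss_halfwidth: int = 7_500,
) -> dict:
    ensure_dir(outdir)
    genome = read_chrom_sizes(paths["genome.chrom.sizes"])
    loops = read_bedpe(paths["loops.bedpe"], column_map={"pet": 6, "p": 7, "q": 8},
                       genome=genome)
    tss = read_tss(paths["tss.bed"])
    pes = read_bed(enhancer_bed, genome)
    tads = TadSet(read_bed(paths["tads.bed"], genome))
    pcg = read_bed(paths["pcg_domains.bed"], genome)
    sig = filter_loops(loops, max_p=max_p)
    sizes = loop_size_distribution(sig)
    hierarchy = default_hierarchy(tss, pes, pcg, tss_halfwidth=tss_halfwidth)
    ann = annotate_partner(sig, pes, hierarchy, anchor_ext=anchor_ext)
    ann.to_csv(os.path.join(outdir, "loop_annotations.tsv"), sep="\t", index=False)
    labels, tad_frac = classify_tad_status(sig, tads)
    summary = interaction_summary(
        sig, pes, tss, anchor_ext=anchor_ext, tss_halfwidth=tss_halfwidth
    )
    self_overlap = loopset_overlap(sig, sig, anchor_ext=anchor_ext)
    report = {
        "stage": "loops",
        "n_loops_raw": len(loops),
        "n_loops_significant": len(sig),
        "size_bin_counts": [int(x) for x in sizes],
        "partner_categories": ann["category"].value_counts().to_dict(),
        "tad_fractions": tad_frac,
        "interaction_summary": {
            k: v for k, v in summary.items() if k != "interacting_genes"
        },
        "self_overlap_pct": self_overlap,
    }
    _dump_json(os.path.join(outdir, "loop_summary.json"), report)
    report["interacting_genes"] = summary["interacting_genes"]
    return report


def stage_pileup(
    paths: dict,
    outdir: str,
    halfwidth: int = 250_000,
    normalization: str = "expected",
    seed: int = 0,
    chrom: str = "chrC",
) -> dict:
    ensure_dir(outdir)
    pairs_loops = read_bedpe(paths["contact_pairs.bedpe"])
    if len(pairs_loops) == 0:
        raise ConfigurationError("pileup: no locus pairs supplied")
    cfg_res = _coo_resolution(paths["contacts.coo.tsv"])
    n_bins = _coo_nbins(paths["contacts.coo.tsv"])
    cm = read_coo(paths["contacts.coo.tsv"], chrom, n_bins * cfg_res, cfg_res)
    pairs = [(lp.anchor1, lp.anchor2) for lp in pairs_loops]
    result = pileup(
        cm, pairs, halfwidth=halfwidth, normalization=normalization, seed=seed
    )
    np.savetxt(
        os.path.join(outdir, "pileup_window.tsv"),
        result.mean_window,
        delimiter="\t",
        fmt="%.6g",
    )
    report = {
        "stage": "pileup",
        "n_pairs_used": result.n_pairs_used,
        "n_pairs_skipped": result.n_pairs_skipped,
        "loopiness": round(result.loopiness, 6) if result.loopiness else None,
        "normalization": normalization,
    }
    _dump_json(os.path.join(outdir, "pileup_summary.json"), report)
    return report


def _coo_resolution(path) -> int:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#resolution="):
        return int(first.split("=", 1)[1])
    return 5_000


def _coo_nbins(path) -> int:
    top = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split("\t")
            top = max(top, int(f[0]), int(f[1]))
    return top + 1


def run_all(cfg: SimConfig, outdir: str) -> dict:
    """Simulate, then run every stage on the files just written.

    The final run report (JSON) is deterministic for a fixed config/seed;
    wall-clock per stage is logged, not written.
    """
    ensure_dir(outdir)
    simdir = os.path.join(outdir, "simulated")
    report = {"version": __version__, "seed": cfg.seed}
    sections = []

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        section = fn(*args, **kwargs)
        logger.info("stage %s took %.2fs", name, time.perf_counter() - t0)
        sections.append(section)
        return section

    timed("simulate", stage_simulate, cfg, simdir)
    with open(os.path.join(simdir, "paths.json")) as fh:
        paths = {k: os.path.join(simdir, v) for k, v in json.load(fh).items()}
    calls = timed(
        "call_enhancers", stage_call_enhancers, paths,
        os.path.join(outdir, "enhancers"), cfg.contexts,
    )
    merged_pe_bed = os.path.join(outdir, "enhancers", "enhancers_pe_all.bed")
    timed("conserve", stage_conserve, paths, os.path.join(outdir, "conservation"),
          merged_pe_bed)
    loops_section = timed(
        "loops", stage_loops, paths, os.path.join(outdir, "loops"), merged_pe_bed
    )
    timed(
        "associate", stage_associate, paths, os.path.join(outdir, "association"),
        merged_pe_bed, interacting_genes=loops_section.pop("interacting_genes"),
    )
    timed("pileup", stage_pileup, paths, os.path.join(outdir, "pileup"),
          seed=cfg.seed)
    report["config_hash"] = config_hash(
        {k: str(v) for k, v in vars(cfg).items()}
    )
    report["stages"] = sections
    _dump_json(os.path.join(outdir, "run_report.json"), report)
    lines = [f"# run report (config {report['config_hash']})"]
    for s in sections:
        lines.append(f"## {s['stage']}")
        for k, v in s.items():
            if k != "stage":
                lines.append(f"- {k}: {v}")
    with open(os.path.join(outdir, "run_report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return report
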