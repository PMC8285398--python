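#!/usr/bin/env python
"""Genetic and epigenetic associations of the poised enhancers.

Measures distances from enhancers to CpG islands, classifies promoter
chromatin states (bivalent / H3K27me3-only / H3K4me3-only / unmarked) from
TSS-window mark overlap, assigns nearest genes, and tests whether genes
interacting with enhancers (from the loop stage) are enriched for bivalent
promoters (two-sided Fisher exact test, sample odds ratio).
"""

import argparse
import json
import os

from poisedloop.pipeline import stage_associate

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--enhancers", default="results/enhancers/enhancers_pe_all.bed")
    ap.add_argument("--loops", default="results/loops/loop_annotations.tsv")
    ap.add_argument("--out", default="results/association")
    args = ap.parse_args()
    with open(os.path.join(args.data, "paths.json")) as fh:
        paths = {k: os.path.join(args.data, v) for k, v in json.load(fh).items()}
    # genes interacting with enhancers: promoter-category partner anchors
    import pandas as pd

    from poisedloop.intervals import GenomicInterval, IntervalSet, intersect, tss_windows
    from poisedloop.io import read_tss

    tss = read_tss(paths["tss.bed"])
    genes = []
    if os.path.exists(args.loops):
        ann = pd.read_csv(args.loops, sep="\t")
        partners = IntervalSet(
            [
                GenomicInterval(r.partner_chrom, r.partner_start, r.partner_end)
                for r in ann.itertuples()
            ]
        )
        windows = tss_windows(tss, 7_500)
        genes = sorted({w.name for w in intersect(windows, partners, "select")})
    section = stage_associate(paths, args.out, args.enhancers, interacting_genes=genes)
    print(json.dumps(section, indent=2))
    print("\nDistance and state tables are under results/association/.")
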