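#!/usr/bin/env python
"""Classify poised / active / primed / PoiAct enhancers from the peak files.

Applies the combinatorial mark rules per cellular context (open chromatin
with H3K4me1 plus H3K27me3 for poised, plus H3K27ac for active; H3K4me1
alone for primed), resolves cross-class overlaps, and relabels poised
elements gaining later-stage H3K27ac as PoiAct. Outputs one BED per class
plus a provenance table under results/enhancers/.
"""

import argparse
import json
import os

from poisedloop.pipeline import stage_call_enhancers

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/enhancers")
    args = ap.parse_args()
    with open(os.path.join(args.data, "paths.json")) as fh:
        paths = {k: os.path.join(args.data, v) for k, v in json.load(fh).items()}
    section = stage_call_enhancers(paths, args.out)
    print(json.dumps(section, indent=2))
    print(
        "\nCall counts above should match the planted per-class counts in "
        f"{args.data}/truth_manifest.json (primed may gain calls from noise "
        "H3K4me1 peaks, which carry the full primed signature by definition)."
    )
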