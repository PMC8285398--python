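# poisedloop

Poised enhancers are distal regulatory elements of major developmental
genes that are already bookmarked in pluripotent cells: they show open
chromatin, p300 binding and H3K4me1 like active enhancers, but carry
Polycomb-deposited H3K27me3 instead of H3K27ac, sit near orphan CpG
islands, and physically contact their (often bivalent) target promoters
before activation. `poisedloop` implements the computational workflow used
to characterise such elements from epigenomic interval data:

* **Rule-based enhancer classification** — poised, active, primed and
  PoiAct (poised elements that gain H3K27ac in a later cell state) classes
  from multi-context ChIP/ATAC peak sets, via BED-style set algebra
  (intersect / subtract / merge / union) with inclusive fold-enrichment
  and significance thresholds, TSS-proximity filtering, and full per-call
  provenance. In-vivo (p-value thresholded, no H3K4me1) and de novo
  (±2.5 kb extension, strictly >10 kb from TSS) rule variants are included.
* **Cross-species conservation** — UCSC chain parsing and interval
  remapping; an element is conserved when the fraction of its bases inside
  aligned blocks of the best overlapping chain (the liftOver `-minMatch`
  semantic) clears a threshold, swept over 0.2–0.99.
* **Association statistics** — distances to CpG islands, promoter
  chromatin states (bivalent / H3K27me3-only / H3K4me3-only / unmarked),
  two-sided Fisher exact enrichment with the sample odds ratio
  `(a·d)/(b·c)`, exact/approximate Wilcoxon rank-sum comparisons, Polycomb
  domain calling (EED ∩ RING1B), nearest-gene assignment.
* **Loop topology** — BEDPE loop lists filtered by significance, size
  distributions (short / mid-range 300 kb–1 Mb / long), hierarchical
  partner annotation (promoter ±7.5 kb > enhancer > PcG domain > other)
  under ±10 kb anchor extension, intra/inter-TAD classification by anchor
  midpoints, and anchor-extended loop-set overlap.
* **Contact-matrix pileups** — coverage normalization and Knight–Ruiz
  balancing (symmetric iterative proportional fitting to the KR fixed
  point), snippet pileups ±250 kb around locus pairs with expected- or
  shift-based controls, and the **loopiness** statistic: the center pixel
  of the averaged window divided by the mean of its four corner pixels.
* **Synthetic data with planted truth** — a generator that emits every
  input format the pipeline reads (narrowPeak/broadPeak, BED, BEDPE, UCSC
  chain, COO contact matrices, chrom.sizes) with a machine-readable truth
  manifest, so that every stage's output is exactly predictable.

## Worked example

Run the numbered analysis drivers (each is a thin wrapper over the library
and writes tables under `results/`), or equivalently
`poisedloop run-all --seed 0 --out results`:

```bash
python analysis/01_simulate.py --seed 0     # synthetic data + truth manifest
python analysis/02_call_enhancers.py        # classify the four classes
python analysis/03_conservation.py          # threshold sweep over the chain
python analysis/04_loop_topology.py         # loop filtering + annotation
python analysis/05_association.py           # CGI / promoter-state statistics
python analysis/06_pileup.py                # pileup + loopiness
```

With seed 0 the classifier reports

```json
{"counts": {"poised": 60, "active": 60, "primed": 123, "poiact": 30}}
```

recovering all 200 planted elements with their planted classes (the extra
primed calls are surviving noise H3K4me1 peaks — a lone H3K4me1 peak *is*
the primed signature). The conservation sweep over the 90 poised-class
elements returns fractions `0.83, 0.67, 0.50, 0.33, 0.33, 0.17` at mapping
ratios `0.2 … 0.99` — non-increasing and equal to the planted ratio levels.
The loop stage keeps 95 of 120 loops at p ≤ 0.01 and annotates their
partners exactly as planted (`promoter: 30, seed: 30, pcg_domain: 15,
other: 20`; the 15 enhancer–enhancer loops count once per seed anchor),
with 66.67% of distal enhancers interacting with at least one locus and
31.58% of those interactions landing on promoters. The pileup over 100
planted pairs reports

```json
{"n_pairs_used": 100, "loopiness": 4.908006}
```

recovering the generator's 5-fold center enrichment to within sampling
noise.

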