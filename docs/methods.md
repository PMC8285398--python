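# Methods

## Coordinate and interval conventions

All coordinates are 0-based, half-open (BED semantics), everywhere in
memory and on disk; 1-based formats must be converted at the reader
boundary. `merge` collapses bookended intervals (a gap of 0 is mergeable),
matching bedtools-merge defaults. Distances between intervals are
closest-edge gaps — 0 on overlap, and also 0 for bookended intervals,
which share no base; tests therefore assert "overlap ⇒ distance 0" and
"distance > 0 ⇒ no overlap" rather than a biconditional. Nearest-feature
ties break to the leftmost subject by (chrom, start, end) so outputs are
deterministic. TSS windows are strand-ignored: an element is *proximal* at
half-width `h` iff its minimum base distance to the TSS base is ≤ `h`
(window `[t−h, t+h+1)`), which makes the de novo "strictly more than
10 kb" rule exclude an element starting exactly 10 kb away. Signal
metaprofiles anchor windows at region midpoints because enhancer elements
have heterogeneous widths; uncovered and out-of-genome bases contribute
zero to a bin's base-weighted mean.

## Enhancer classification

Classes are combinatorial predicates over filtered peak sets per cellular
context:

| class  | requires (same context)              | forbids (any context) |
|--------|--------------------------------------|-----------------------|
| poised | open chromatin ∩ (H3K27me3 ∩ H3K4me1)| H3K27ac               |
| active | open chromatin ∩ (H3K27ac ∩ H3K4me1) | H3K27me3              |
| primed | H3K4me1                              | H3K27ac, H3K27me3     |
| poiact | poised + later-stage H3K27ac         | —                     |

Default thresholds: narrow open-chromatin peaks (ATAC or p300) at
q ≤ 0.05 with fold enrichment ≥ 4; broad histone peaks at q ≤ 0.1 with
fold ≥ 5 (H3K27ac) or ≥ 2 (H3K4me1, H3K27me3), extended ±1 kb. All
comparisons are inclusive. Marks are combined within a context before
contexts are pooled (UNION), then the TSS ±5 kb filter and the subtraction
of the repulsive mark's cross-context union are applied, then MERGE.

Two genuinely open choices, and how they were fixed:

* *Subtraction granularity.* Removing H3K27ac-marked candidates is
  element-level by default — one overlapping base discards the whole
  candidate — because the classes count unique elements and base-level
  subtraction would fragment them; the base-level variant is retained
  (`element_level_subtraction=False`) and used by the oracle tests.
* *Filter order.* The TSS filter runs before the subtraction (the order
  the protocol text implies); `tss_filter_first=False` swaps them. The two
  orders give identical results whenever both filters are element-level,
  as here.

Cross-class redundancy: elements overlapping between poised and either
other class are dropped from both; active∩primed overlaps are attributed
to active. The in vivo variant needs no H3K4me1, uses p ≤ 0.01 (not q) on
histone marks with fold ≥ 2 and ATAC fold ≥ 5, subtracts both in vivo and
in vitro H3K27ac, and applies the TSS filter last. De novo calling extends
histone peaks ±2.5 kb, uses q ≤ 0.1 throughout with species-specific fold
thresholds, and skips the H3K27ac subtraction (with a logged notice) when
no H3K27ac data exists. Every call carries a provenance trace of the rule
steps that produced it.

Replicated later-stage H3K27ac sets are segment-intersected across
replicates before use (a peak present in one of two replicates does not
count), then extended and unioned.

## Conservation scoring

A UCSC chain aligns a source genome (`t` header fields) to a target (`q`
fields); block span sums are validated against the header on parse. An
interval's *mapped ratio* is the fraction of its bases inside aligned
blocks of the single highest-scoring overlapping chain — no cross-chain
stitching, matching liftOver's default. The target interval is the
bounding span of the mapped bases on the target's forward strand
(− strand chains are reflected through `q_size`); targets expanding beyond
10× the query length (configurable) are rejected as pathological. The
"mappability/identity threshold" is interpreted as this coverage ratio,
compared inclusively; sequence-level percent identity is not computed
since only chain files are consumed. Threshold sweeps map once and
re-threshold the cached ratios, so fractions are non-increasing by
construction.

## Statistics

* **Fisher exact** (scipy): two-sided p by summing hypergeometric
  probabilities ≤ the observed table's; the reported odds ratio is the
  sample cross-product `(a·d)/(b·c)` (a reproducible closed form; the
  conditional-MLE variant differs and is not used). A zero margin yields a
  missing odds ratio and p = 1 with a warning. The test suite validates p
  against full enumeration over fixed-margin tables.
* **Rank-sum** (scipy Mann–Whitney): exact null distribution when the
  pooled sample has ≤ 25 tie-free values, otherwise the normal
  approximation with tie and continuity corrections. Fold changes are
  ratios of means by default (medians selectable); a zero denominator
  yields a missing fold change.
* **Promoter states** partition the gene universe by H3K4me3/H3K27me3
  overlap of the TSS window, default ±1 kb (the window size is not implied
  by any consumed annotation, so it is an explicit, documented default).
* **PcG domains** are the merged segment-intersection of the EED and
  RING1B consensus peak sets, each consensus being the intersection of its
  replicates.

## Loop topology

Loop size is the distance between anchor midpoints (invariant to anchor
width). Significance filtering keeps values ≤ the threshold on the chosen
column (p or q, exactly one). Size histogram bins are half-open with
default edges 0 / 300 kb / 1 Mb / ∞. Partner annotation selects loops
whose anchor ±10 kb overlaps a seed element and labels the *other* anchor
with the first matching category of an ordered hierarchy, default
promoter (TSS ±7.5 kb) > seed-class element > PcG domain > other; the
hierarchy order is a declared configuration default. A loop whose two
anchors both touch seeds contributes one row per orientation and its
partner falls into the seed category. TAD status uses anchor midpoints
(an anchor straddling a boundary belongs to one TAD); loops with a
midpoint in no TAD are unassigned and excluded from the intra/inter
fractions. Loop-set overlap extends the query's anchors by ±10 kb and
requires both anchors of some subject loop to overlap; the measure is
directional (self-overlap is 100%, symmetry is not guaranteed).

## Contact matrices, pileups, loopiness

Matrices are per-chromosome, symmetric, dense in memory with a sparse
upper-triangle text representation on disk; at the few-hundred-bin scale
this package targets, dense storage is a few megabytes. Coverage
normalization divides each entry by the product of scaled marginals
`w_i = m_i / mean(m)` over covered bins and masks zero-coverage bins; the
weights are scale-invariant, so a global count factor passes through
uniformly and pileup enrichment ratios are unchanged. Balancing runs
symmetric iterative proportional fitting to the Knight–Ruiz fixed point
(`x ← x / sqrt(x ∘ Ax)`), targeting unit row sums on covered bins within
`tol = 1e−6` (default, max 3000 iterations; non-convergence raises with
the last residual). Disconnected covered components balance independently
under the per-row target.

Pileups extract `(2w+1)²` snippets (`w` = half-width / resolution,
half-width default 250 kb) centred on each pair's midpoint bins (ties to
the lower bin; the upstream locus indexes rows), divide each snippet by a
control, and average pixel-wise ignoring missing values. Two controls are
provided because tool defaults in this area are ambiguous: *expected* (the
matrix's per-diagonal mean at each pixel's genomic separation) and
*shifts* (the mean of `n_shifts` snippets displaced along the diagonal by
seeded uniform offsets in ±[w, 10w] bins); on loop-free decay matrices the
two agree within sampling noise. Pairs closer than the half-width to a
chromosome edge are skipped and counted. **Loopiness** is the central
pixel of the averaged window divided by the mean of its four `k×k` corner
blocks (default k = 1, single pixels); missing corner pixels are excluded
and an all-missing corner set yields a missing value. Loopiness is
invariant to global rescaling of the window.

## Synthetic data: what it emulates, and what it does not

The generator plants 200 enhancer elements (60 poised, 60 active, 50
primed, 30 PoiAct) across two 6 Mb chromosomes in three pluripotent
contexts, 40 TSS with promoter states cycled over the four classes, CGIs
(75% of poised-class elements get one within 3 kb, emulating the strong
CGI proximity of poised enhancers), TADs tiling each chromosome (400 kb
with 50 kb gaps), 12 PcG domains, ~120 loops over five planted categories
with p/q values straddling the 0.01/0.1 thresholds, and a 500-bin contact
matrix at 5 kb resolution with Poisson counts around a
`(1+d)^−α` decay (α = 1, diagonal intensity 2000) and planted 5-fold
center enrichments. Planted features live on a 30 kb slot grid and noise
peaks (default 5/Mb per context and mark, fold enrichments straddling the
class thresholds) on a finer grid kept ≥ 10 kb clear of planted features,
with no two noise peaks overlapping — so noise can never assemble a
multi-mark signature, and every downstream call is exactly predictable
from the truth manifest. One consequence is scored deliberately: a
surviving noise H3K4me1 peak *is* a primed enhancer by definition, so
primed calls have planted recall 100% but not 100% precision under noise,
while the combination classes (poised/active/PoiAct) stay exact.

What the generator does **not** model: replicate-level biological
variability, peak-width/signal correlation structure, sequence content,
chains with rearrangements or many competing alignments, and
trans-chromosomal contacts. Passing the planted-recovery suite therefore
demonstrates the correctness of the implemented rules and statistics
under their stated assumptions, not robustness to the full messiness of
experimental data.

Determinism: every draw comes from `numpy.random.default_rng` seeded from
`SimConfig.seed`; repeated runs produce byte-identical files. The run
report excludes timestamps and machine state for the same reason (stage
wall-clock goes to the log stream only).

## Problem sizes

Default sizes (two 6 Mb chromosomes, 200 elements, 120 loops, 500-bin
matrices, 100 pileup pairs) were chosen so a full end-to-end run completes
in seconds while every statistic retains enough events for its planted
value to be recovered within the stated tolerances (e.g. null loopiness
1 ± 0.1 at 100 pairs; planted enrichment within 15%). The test suite's
randomized oracle comparisons (1000+ interval-algebra instances, 500
chains, 500 Fisher tables, 200 balancing matrices, 100 toy genomes) run
in a few seconds total.
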