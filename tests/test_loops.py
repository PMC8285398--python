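"""Loop lists: parsing, filtering, size bins, partner annotation, TAD status."""

import numpy as np
import pytest
from conftest import ivset

from poisedloop.errors import ConfigurationError, ValidationError
from poisedloop.intervals import GenomicInterval, IntervalSet, TssRecord
from poisedloop.loops import (
    AnnotationHierarchy,
    Loop,
    LoopSet,
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


def mk_loop(s1, e1, s2, e2, p=None, q=None, chrom="chr1"):
    return Loop(GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2),
                p_value=p, q_value=q)


class TestReadBedpe:
    def test_basic_row_and_size(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t0\t10000\tchr1\t50000\t60000\n")
        (lp,) = read_bedpe(p)
        assert lp.size == 50_000

    def test_trans_pairs_excluded(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t0\t10\tchr2\t50\t60\nchr1\t0\t10\tchr1\t50\t60\n")
        assert len(read_bedpe(p)) == 1

    def test_reversed_anchors_canonicalised(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t50000\t60000\tchr1\t0\t10000\n")
        (lp,) = read_bedpe(p)
        assert lp.anchor1.start == 0 and lp.anchor2.start == 50_000

    def test_overlapping_anchors_rejected(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t0\t10000\tchr1\t5000\t20000\n")
        with pytest.raises(ValidationError):
            read_bedpe(p)

    def test_column_map_for_stats(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t0\t100\tchr1\t5000\t5100\t12\t0.005\t0.01\n")
        (lp,) = read_bedpe(p, column_map={"pet": 6, "p": 7, "q": 8})
        assert lp.pet_count == 12 and lp.p_value == 0.005


class TestFilterLoops:
    def test_threshold_inclusive_and_column_choice(self):
        loops = LoopSet([
            mk_loop(0, 100, 5_000, 5_100, p=0.005, q=0.2),
            mk_loop(0, 100, 9_000, 9_100, p=0.05, q=0.05),
        ])
        kept = filter_loops(loops, max_p=0.01)
        assert len(kept) == 1 and kept[0].p_value == 0.005
        kept_q = filter_loops(loops, max_q=0.1)
        assert len(kept_q) == 1 and kept_q[0].q_value == 0.05
        assert len(filter_loops(loops, max_p=1.0)) == 2

    def test_missing_column_is_configuration_error(self):
        loops = LoopSet([mk_loop(0, 100, 5_000, 5_100)])
        with pytest.raises(ConfigurationError):
            filter_loops(loops, max_p=0.01)
        with pytest.raises(ConfigurationError):
            filter_loops(loops)


class TestSizeDistribution:
    def test_default_bins(self):
        loops = LoopSet([
            mk_loop(0, 1_000, 100_000, 101_000),       # ~100 kb
            mk_loop(0, 1_000, 500_000, 501_000),       # ~500 kb
            mk_loop(0, 1_000, 2_000_000, 2_001_000),   # ~2 Mb
        ])
        assert loop_size_distribution(loops).tolist() == [1, 1, 1]

    def test_empty_and_boundary(self):
        assert loop_size_distribution(LoopSet([])).tolist() == [0, 0, 0]
        # size exactly 300 kb falls in the mid-range bin (half-open)
        lp = mk_loop(0, 1_000, 300_000, 301_000)
        assert lp.size == 300_000
        assert loop_size_distribution(LoopSet([lp])).tolist() == [0, 1, 0]


class TestAnnotatePartner:
    def test_hierarchy_order_wins(self):
        seeds = ivset(("chr1", 100_000, 101_000))
        tss = [TssRecord("g", "chr1", 200_000)]
        pcg = ivset(("chr1", 195_000, 205_000))
        hierarchy = default_hierarchy(tss, seeds, pcg)
        # partner anchor overlaps both the TSS window and the PcG domain
        loops = LoopSet([mk_loop(99_000, 102_000, 198_000, 202_000)])
        ann = annotate_partner(loops, seeds, hierarchy)
        assert ann["category"].tolist() == ["promoter"]

    def test_seed_with_no_loops_noninteracting(self):
        seeds = ivset(("chr1", 100_000, 101_000))
        hierarchy = default_hierarchy([], seeds)
        ann = annotate_partner(LoopSet([]), seeds, hierarchy)
        assert len(ann) == 0

    def test_anchor_extension_selects_nearby_seed(self):
        seeds = ivset(("chr1", 100_000, 101_000))
        hierarchy = default_hierarchy([], seeds)
        # anchor 9 kb from the seed: selected at 10 kb extension
        loops = LoopSet([mk_loop(110_000, 111_000, 300_000, 301_000)])
        ann = annotate_partner(loops, seeds, hierarchy, anchor_ext=10_000)
        assert len(ann) == 1 and ann["category"].iloc[0] == "other"
        ann8 = annotate_partner(loops, seeds, hierarchy, anchor_ext=8_000)
        assert len(ann8) == 0

    def test_seed_seed_loop_counts_per_orientation(self):
        seeds = ivset(("chr1", 100_000, 101_000), ("chr1", 300_000, 301_000))
        hierarchy = default_hierarchy([], seeds)
        loops = LoopSet([mk_loop(99_500, 101_500, 299_500, 301_500)])
        ann = annotate_partner(loops, seeds, hierarchy)
        assert len(ann) == 2 and set(ann["category"]) == {"seed"}

    def test_counts_sum_to_selected_rows(self):
        seeds = ivset(("chr1", 100_000, 101_000))
        tss = [TssRecord("g", "chr1", 500_000)]
        hierarchy = default_hierarchy(tss, seeds)
        loops = LoopSet([
            mk_loop(99_000, 102_000, 499_000, 501_000),
            mk_loop(99_000, 102_000, 800_000, 801_000),
            mk_loop(700_000, 701_000, 900_000, 901_000),  # no seed anchor
        ])
        ann = annotate_partner(loops, seeds, hierarchy)
        assert ann["category"].value_counts().sum() == 2

    def test_empty_hierarchy_rejected(self):
        with pytest.raises(ConfigurationError):
            AnnotationHierarchy([])


class TestTadStatus:
    TADS = TadSet(ivset(("chr1", 0, 100_000), ("chr1", 200_000, 300_000)))

    def test_intra_inter_unassigned(self):
        loops = LoopSet([
            mk_loop(9_000, 11_000, 49_000, 51_000),      # both in TAD 1
            mk_loop(9_000, 11_000, 249_000, 251_000),    # different TADs
            mk_loop(9_000, 11_000, 149_000, 151_000),    # right anchor in gap
        ])
        labels, frac = classify_tad_status(loops, self.TADS)
        assert labels == ["intra", "inter", "unassigned"]
        assert frac["pct_intra"] == 50.0 and frac["pct_inter"] == 50.0
        assert frac["n_intra"] + frac["n_inter"] + frac["n_unassigned"] == len(loops)

    def test_matches_brute_force_scan(self, rng):
        tads = ivset(*[("chr1", s, s + 50_000) for s in range(0, 1_000_000, 80_000)])
        tset = TadSet(tads)
        tad_list = [(iv.start, iv.end) for iv in tads]

        def brute(pos):
            hits = [i for i, (s, e) in enumerate(tad_list) if s <= pos < e]
            return hits[0] if hits else None

        loops = []
        for _ in range(100):
            a = int(rng.integers(0, 900_000))
            b = a + int(rng.integers(10_000, 90_000))
            loops.append(mk_loop(a, a + 1_000, b, b + 1_000))
        labels, _ = classify_tad_status(LoopSet(loops), tset)
        for lp, lab in zip(loops, labels):
            t1, t2 = brute(lp.anchor1.midpoint), brute(lp.anchor2.midpoint)
            want = (
                "unassigned" if (t1 is None or t2 is None)
                else "intra" if t1 == t2 else "inter"
            )
            assert lab == want

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValidationError):
            TadSet(ivset(("chr1", 0, 100), ("chr1", 50, 150)))


class TestLoopsetOverlap:
    def test_self_overlap_is_100(self):
        loops = LoopSet([mk_loop(0, 5_000, 100_000, 105_000)])
        assert loopset_overlap(loops, loops, anchor_ext=0) == 100.0

    def test_shift_within_and_beyond_extension(self):
        a = LoopSet([mk_loop(100_000, 105_000, 400_000, 405_000)])
        shift5 = LoopSet([mk_loop(105_000, 110_000, 405_000, 410_000)])
        shift25 = LoopSet([mk_loop(125_000, 130_000, 425_000, 430_000)])
        assert loopset_overlap(a, shift5, anchor_ext=10_000) == 100.0
        assert loopset_overlap(a, shift25, anchor_ext=10_000) == 0.0


class TestInteractionSummary:
    def test_single_pe_promoter_loop(self):
        tss = [TssRecord("g", "chr1", 500_000)]
        pes = ivset(("chr1", 100_000, 101_000), ("chr1", 800_000, 801_000))
        loops = LoopSet([mk_loop(99_000, 102_000, 498_000, 502_000)])
        s = interaction_summary(loops, pes, tss)
        assert s["n_distal_pes"] == 2
        assert s["n_interacting_pes"] == 1
        assert s["pct_pes_interacting"] == 50.0
        assert s["pct_interactions_with_promoter"] == 100.0
        assert s["interacting_genes"] == ["g"]

    def test_proximal_pe_excluded_from_distal_subset(self):
        tss = [TssRecord("g", "chr1", 500_000)]
        # PE 9 kb from the TSS: not part of the distal subset
        pes = ivset(("chr1", 509_000, 510_000))
        s = interaction_summary(LoopSet([]), pes, tss)
        assert s["n_distal_pes"] == 0
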