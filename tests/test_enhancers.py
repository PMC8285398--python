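"""Enhancer classification rules on hand-built toy loci and against a
literal per-base rule evaluator."""

import numpy as np
import pytest
from conftest import ivset
from oracles import literal_enhancer_rules

from poisedloop.enhancers import (
    CallingParams,
    EnhancerCall,
    LaterAcSet,
    MarkLibrary,
    call_active_invitro,
    call_poiact,
    call_poised_denovo,
    call_poised_invitro,
    call_poised_invivo,
    call_primed_invitro,
    filter_peaks,
    resolve_class_overlaps,
    set_overlap_report,
)
from poisedloop.errors import ConfigurationError
from poisedloop.intervals import GenomicInterval, IntervalSet, TssRecord
from poisedloop.io import PeakRecord

GENOME = {"chr1": 200_000}


def pk(s, e, fold=10.0, q=1e-4, p=None, chrom="chr1"):
    return PeakRecord(
        interval=GenomicInterval(chrom, s, e),
        fold_enrichment=fold,
        p_value=p if p is not None else (q / 2 if q is not None else None),
        q_value=q,
    )


def spans(calls):
    return sorted((c.interval.start, c.interval.end) for c in calls)


class TestFilterPeaks:
    def test_fold_threshold_inclusive(self):
        kept = filter_peaks([pk(0, 10, fold=4.0)], min_fold=4)
        assert len(kept) == 1
        assert filter_peaks([pk(0, 10, fold=3.9)], min_fold=4) == []

    def test_q_and_p_thresholds(self):
        assert len(filter_peaks([pk(0, 10, q=0.1)], max_q=0.1)) == 1
        assert filter_peaks([pk(0, 10, q=0.2)], max_q=0.1) == []
        # missing value with an enabled threshold drops the record
        rec = PeakRecord(GenomicInterval("chr1", 0, 10), 5.0, None, None)
        assert filter_peaks([rec], max_q=0.1) == []
        assert len(filter_peaks([rec])) == 1

    def test_empty_input(self):
        assert filter_peaks([], min_fold=4) == []


def library(entries):
    lib = MarkLibrary(genome=GENOME)
    for (ctx, mark), peaks in entries.items():
        lib.add(ctx, mark, peaks)
    return lib


TSS = [TssRecord("gA", "chr1", 6_000, "+")]


def base_library(extra=()):
    """One distal locus at 50 kb with the full poised signature in both
    contexts, plus whatever ``extra`` entries add/override."""
    entries = {
        ("c1", "ATAC"): [pk(50_000, 51_000, fold=6, q=1e-3)],
        ("c1", "H3K4me1"): [pk(50_000, 51_000, fold=3, q=1e-3)],
        ("c1", "H3K27me3"): [pk(50_000, 51_000, fold=3, q=1e-3)],
        ("c1", "H3K27ac"): [],
        ("c2", "ATAC"): [],
        ("c2", "H3K4me1"): [],
        ("c2", "H3K27me3"): [],
        ("c2", "H3K27ac"): [],
    }
    entries.update(dict(extra))
    return library(entries)


class TestPoisedInvitro:
    def test_full_signature_distal_is_poised(self):
        calls = call_poised_invitro(base_library(), ["c1", "c2"], TSS, CallingParams())
        assert spans(calls) == [(50_000, 51_000)]
        assert calls[0].enhancer_class == "poised"
        assert calls[0].provenance  # rule trace recorded

    def test_k27ac_in_any_context_kills_element(self):
        lib = base_library({("c2", "H3K27ac"): [pk(50_500, 50_700, fold=6, q=1e-3)]})
        assert call_poised_invitro(lib, ["c1", "c2"], TSS, CallingParams()) == []

    def test_tss_proximal_element_removed(self):
        lib = base_library(
            {
                ("c1", "ATAC"): [pk(8_000, 9_000, fold=6, q=1e-3)],
                ("c1", "H3K4me1"): [pk(8_000, 9_000, fold=3, q=1e-3)],
                ("c1", "H3K27me3"): [pk(8_000, 9_000, fold=3, q=1e-3)],
            }
        )  # 2 kb from the TSS at 6 000
        assert call_poised_invitro(lib, ["c1", "c2"], TSS, CallingParams()) == []

    def test_marks_are_not_pooled_across_contexts(self):
        # K27me3 only in c2 while ATAC/K4me1 only in c1: no call
        lib = base_library(
            {
                ("c1", "H3K27me3"): [],
                ("c2", "H3K27me3"): [pk(50_000, 51_000, fold=3, q=1e-3)],
            }
        )
        assert call_poised_invitro(lib, ["c1", "c2"], TSS, CallingParams()) == []

    def test_missing_mark_raises_configuration_error(self):
        lib = library({("c1", "ATAC"): [pk(50_000, 51_000)]})
        with pytest.raises(ConfigurationError, match="H3K27me3"):
            call_poised_invitro(lib, ["c1"], TSS, CallingParams())

    def test_raising_min_fold_never_adds_calls(self):
        lib = base_library(
            {("c1", "ATAC"): [pk(50_000, 51_000, fold=5), pk(80_000, 81_000, fold=4.2)],
             ("c1", "H3K4me1"): [pk(50_000, 51_000, fold=3), pk(80_000, 81_000, fold=3)],
             ("c1", "H3K27me3"): [pk(50_000, 51_000, fold=3), pk(80_000, 81_000, fold=3)]}
        )
        from poisedloop.enhancers import MarkFilter

        counts = []
        for mf in (4.0, 4.5, 5.0, 5.5):
            params = CallingParams(filters={"ATAC": MarkFilter(min_fold=mf, max_q=0.05)})
            counts.append(len(call_poised_invitro(lib, ["c1", "c2"], TSS, params)))
        assert counts == sorted(counts, reverse=True)


class TestActivePrimed:
    def test_active_mirror_rule(self):
        lib = base_library(
            {
                ("c1", "H3K27me3"): [],
                ("c1", "H3K27ac"): [pk(50_000, 51_000, fold=6, q=1e-3)],
            }
        )
        calls = call_active_invitro(lib, ["c1", "c2"], TSS, CallingParams())
        assert spans(calls) == [(50_000, 51_000)]
        # adding K27me3 in the other context removes it
        lib2 = base_library(
            {
                ("c1", "H3K27me3"): [],
                ("c1", "H3K27ac"): [pk(50_000, 51_000, fold=6, q=1e-3)],
                ("c2", "H3K27me3"): [pk(50_400, 50_600, fold=3, q=1e-3)],
            }
        )
        assert call_active_invitro(lib2, ["c1", "c2"], TSS, CallingParams()) == []

    def test_primed_is_k4me1_only(self):
        lib = base_library({("c1", "ATAC"): [], ("c1", "H3K27me3"): []})
        calls = call_primed_invitro(lib, ["c1", "c2"], TSS, CallingParams())
        # K4me1 broad peaks are extended +-1 kb by the rule
        assert spans(calls) == [(49_000, 52_000)]
        for bad_mark in ("H3K27ac", "H3K27me3"):
            lib2 = base_library(
                {("c1", "ATAC"): [], ("c1", "H3K27me3"): [],
                 ("c2", bad_mark): [pk(50_400, 50_600, fold=6, q=1e-3)]}
            )
            assert call_primed_invitro(lib2, ["c1", "c2"], TSS, CallingParams()) == []

    def test_no_contexts_warns_and_returns_empty(self):
        assert call_primed_invitro(base_library(), [], TSS, CallingParams()) == []


def mk_calls(cls, *coords):
    return [
        EnhancerCall(GenomicInterval("chr1", s, e), cls) for s, e in coords
    ]


class TestResolveOverlaps:
    def test_active_primed_overlap_goes_to_active(self):
        res = resolve_class_overlaps(
            mk_calls("poised", (0, 1_000)),
            mk_calls("active", (5_000, 6_000)),
            mk_calls("primed", (5_500, 6_500)),
        )
        assert spans(res["active"]) == [(5_000, 6_000)]
        assert res["primed"] == []
        assert spans(res["poised"]) == [(0, 1_000)]

    def test_poised_active_overlap_removed_from_both(self):
        res = resolve_class_overlaps(
            mk_calls("poised", (5_000, 6_000)),
            mk_calls("active", (5_500, 6_500)),
            mk_calls("primed", (9_000, 9_500)),
        )
        assert res["poised"] == [] and res["active"] == []
        assert spans(res["primed"]) == [(9_000, 9_500)]

    def test_disjoint_inputs_unchanged(self):
        res = resolve_class_overlaps(
            mk_calls("poised", (0, 1_000)),
            mk_calls("active", (5_000, 6_000)),
            mk_calls("primed", (9_000, 9_500)),
        )
        assert all(len(v) == 1 for v in res.values())


class TestPoiAct:
    def test_later_k27ac_relabels(self):
        poised = mk_calls("poised", (50_000, 51_000), (80_000, 81_000))
        later = [LaterAcSet(replicates=[[pk(50_200, 50_800, fold=6, q=1e-3)]])]
        poiact, still = call_poiact(poised, later, GENOME)
        assert spans(poiact) == [(50_000, 51_000)]
        assert spans(still) == [(80_000, 81_000)]
        assert poiact[0].enhancer_class == "poiact"

    def test_replicates_are_intersected_first(self):
        poised = mk_calls("poised", (50_000, 51_000))
        one_of_two = [
            LaterAcSet(
                replicates=[[pk(50_200, 50_800, fold=6, q=1e-3)], []],
                extension=0,
            )
        ]
        poiact, still = call_poiact(poised, one_of_two, GENOME)
        assert poiact == [] and len(still) == 1

    def test_empty_later_sets(self):
        poised = mk_calls("poised", (50_000, 51_000))
        poiact, still = call_poiact(poised, [], GENOME)
        assert poiact == [] and len(still) == 1


class TestInVivo:
    def test_p_value_thresholds_and_fc5(self):
        atac = [pk(50_000, 51_000, fold=6, q=1e-3)]
        # insignificant q but significant p: the in vivo rule uses p
        k27me3 = [pk(50_000, 51_000, fold=3, q=0.5, p=0.005)]
        calls = call_poised_invivo(atac, k27me3, [], ivset(genome=GENOME), TSS, GENOME)
        assert spans(calls) == [(50_000, 51_000)]
        weak_atac = [pk(50_000, 51_000, fold=4.5, q=1e-3)]
        assert call_poised_invivo(weak_atac, k27me3, [], ivset(genome=GENOME), TSS, GENOME) == []

    def test_invitro_k27ac_union_subtracted(self):
        atac = [pk(50_000, 51_000, fold=6, q=1e-3)]
        k27me3 = [pk(50_000, 51_000, fold=3, p=0.005)]
        invitro_ac = ivset(("chr1", 50_400, 50_600), genome=GENOME)
        assert call_poised_invivo(atac, k27me3, [], invitro_ac, TSS, GENOME) == []


class TestDeNovo:
    def test_strict_distal_boundary(self):
        # TSS at 6 000; elements starting exactly 10 kb vs 10 001 bp away
        at_10k = [pk(16_000, 17_000, fold=5, q=1e-3)]
        beyond = [pk(16_001, 17_001, fold=5, q=1e-3)]
        k27 = [pk(15_000, 18_000, fold=5, q=1e-3)]
        assert call_poised_denovo(at_10k, k27, None, TSS, GENOME) == []
        calls = call_poised_denovo(beyond, k27, None, TSS, GENOME)
        assert spans(calls) == [(16_001, 17_001)]

    def test_k27ac_subtraction_skipped_when_unavailable(self):
        open_p = [pk(50_000, 51_000, fold=5, q=1e-3)]
        k27 = [pk(50_000, 51_000, fold=5, q=1e-3)]
        calls = call_poised_denovo(open_p, k27, None, TSS, GENOME)
        assert len(calls) == 1
        assert any("skipped" in step for step in calls[0].provenance)
        # with H3K27ac supplied, the same element is removed
        ac = [pk(50_400, 50_600, fold=5, q=1e-3)]
        assert call_poised_denovo(open_p, k27, ac, TSS, GENOME) == []


class TestOverlapReport:
    def test_reference_style_percentage(self):
        a = IntervalSet(
            [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(3057)]
        )
        b = IntervalSet(
            [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(1213)]
        )
        rep = set_overlap_report(a, b)
        assert rep["a_in_b"] == 1213 and rep["pct_a_in_b"] == 39.68
        assert rep["pct_b_in_a"] == 100.0

    def test_disjoint_and_identical(self):
        a = ivset(("chr1", 0, 10))
        b = ivset(("chr1", 100, 110))
        assert set_overlap_report(a, b)["pct_a_in_b"] == 0.0
        assert set_overlap_report(a, a)["pct_a_in_b"] == 100.0


class TestLiteralOracleEquivalence:
    """Classifier output equals literal per-base rule evaluation on random
    toy genomes."""

    @pytest.mark.parametrize("trial", range(3))
    def test_random_toy_genomes(self, trial):
        rng = np.random.default_rng(7_000 + trial)
        L = 100_000
        for _ in range(10):
            contexts = ["c1", "c2"]
            tss_pos = sorted(int(p) for p in rng.integers(0, L, size=2))
            tss = [TssRecord(f"g{i}", "chr1", p) for i, p in enumerate(tss_pos)]
            lib = MarkLibrary(genome={"chr1": L})
            raw = {}
            for c in contexts:
                for mark in ("ATAC", "H3K4me1", "H3K27me3", "H3K27ac"):
                    peaks = []
                    for _ in range(int(rng.integers(0, 6))):
                        s = int(rng.integers(0, L - 2_000))
                        w = int(rng.integers(200, 1_500))
                        fold = float(rng.uniform(1, 8))
                        q = float(10 ** -rng.uniform(0, 4))
                        peaks.append(pk(s, s + w, fold=fold, q=q))
                    lib.add(c, mark, peaks)
                    raw[(c, mark)] = peaks
            params = CallingParams()
            got = {
                "poised": call_poised_invitro(lib, contexts, tss, params),
                "active": call_active_invitro(lib, contexts, tss, params),
            }
            # literal evaluation on boolean arrays
            masks, open_peaks = {}, {}
            for c in contexts:
                flt = params.filters["ATAC"]
                open_peaks[c] = [
                    p.interval
                    for p in raw[(c, "ATAC")]
                    if p.fold_enrichment >= flt.min_fold and p.q_value <= flt.max_q
                ]
                for mark in ("H3K4me1", "H3K27me3", "H3K27ac"):
                    flt = params.filters[mark]
                    m = np.zeros(L, dtype=bool)
                    for p in raw[(c, mark)]:
                        if p.fold_enrichment >= flt.min_fold and p.q_value <= flt.max_q:
                            m[max(0, p.interval.start - flt.extension):
                              min(L, p.interval.end + flt.extension)] = True
                    masks[(c, mark)] = m
            want = literal_enhancer_rules(masks, open_peaks, tss_pos, L)
            for cls in ("poised", "active"):
                assert spans(got[cls]) == sorted(
                    (iv.start, iv.end) for iv in want[cls]
                ), f"mismatch for {cls}"
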