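"""Chain parsing and interval remapping against a per-base chain walker."""

import numpy as np
import pytest
from oracles import chain_walk_ratio, chain_walk_targets

from poisedloop.conservation import (
    Chain,
    ChainSet,
    conservation_fraction,
    map_interval,
    read_chain,
    threshold_sweep,
    write_chain,
)
from poisedloop.errors import FormatError, ValidationError
from poisedloop.intervals import GenomicInterval, IntervalSet


def identity_chain(length=1_000, chrom="chr1", q_name="chrB1"):
    return Chain(
        score=100.0, t_name=chrom, t_size=length, t_start=0, t_end=length,
        q_name=q_name, q_size=length, q_strand="+", q_start=0, q_end=length,
        chain_id="1", blocks=[(length, 0, 0)],
    )


def random_chain(rng, t_size=10_000) -> Chain:
    """Random alternating aligned/gap blocks on both genomes."""
    blocks = []
    t = int(rng.integers(0, 500))
    t_start = t
    q = int(rng.integers(0, 500))
    q_start = q
    for _ in range(int(rng.integers(1, 10))):
        size = int(rng.integers(50, 600))
        dt = int(rng.integers(0, 400))
        dq = int(rng.integers(0, 400))
        blocks.append((size, dt, dq))
        t += size + dt
        q += size + dq
    size = int(rng.integers(50, 600))
    blocks.append((size, 0, 0))
    t += size
    q += size
    strand = "+" if rng.uniform() < 0.5 else "-"
    return Chain(
        score=float(rng.uniform(1, 1000)), t_name="chr1", t_size=max(t_size, t),
        t_start=t_start, t_end=t, q_name="chrB1", q_size=q + 100,
        q_strand=strand, q_start=q_start, q_end=q, chain_id="r", blocks=blocks,
    )


class TestChainIO:
    def test_single_block_identity_chain(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 100 chr1 1000 + 0 1000 chrB1 1000 + 0 1000 1\n1000\n\n")
        cs = read_chain(p)
        assert len(cs) == 1 and cs.chains[0].blocks == [(1000, 0, 0)]

    def test_span_mismatch_is_format_error(self, tmp_path):
        p = tmp_path / "bad.chain"
        p.write_text("chain 100 chr1 1000 + 0 1000 chrB1 1000 + 0 1000 7\n900\n\n")
        with pytest.raises(FormatError, match="7"):
            read_chain(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.chain"
        p.write_text("")
        assert len(read_chain(p)) == 0

    def test_round_trip(self, tmp_path, rng):
        chains = ChainSet([random_chain(rng) for _ in range(5)])
        p = tmp_path / "rt.chain"
        write_chain(p, chains)
        back = read_chain(p)
        assert [c.blocks for c in back.chains] == [c.blocks for c in chains.chains]


class TestMapInterval:
    def test_identity_chain_full_ratio(self):
        cs = ChainSet([identity_chain()])
        r = map_interval(GenomicInterval("chr1", 100, 200), cs)
        assert r.mapped_ratio == 1.0
        assert (r.target_interval.start, r.target_interval.end) == (100, 200)

    def test_half_covered_query(self):
        c = Chain(
            score=10, t_name="chr1", t_size=1_000, t_start=0, t_end=150,
            q_name="chrB1", q_size=1_000, q_strand="+", q_start=0, q_end=150,
            chain_id="h", blocks=[(150, 0, 0)],
        )
        r = map_interval(GenomicInterval("chr1", 100, 200), ChainSet([c]))
        assert r.mapped_ratio == 0.5

    def test_no_overlapping_chain(self):
        r = map_interval(GenomicInterval("chr9", 0, 100), ChainSet([identity_chain()]))
        assert r.mapped_ratio == 0.0 and r.target_interval is None

    def test_highest_scoring_chain_wins(self):
        low = identity_chain()
        high = Chain(
            score=999, t_name="chr1", t_size=1_000, t_start=0, t_end=100,
            q_name="chrB2", q_size=1_000, q_strand="+", q_start=500, q_end=600,
            chain_id="2", blocks=[(100, 0, 0)],
        )
        r = map_interval(GenomicInterval("chr1", 0, 100), ChainSet([low, high]))
        assert r.chain_id == "2" and r.target_interval.chrom == "chrB2"

    def test_pathological_expansion_rejected(self):
        c = Chain(
            score=10, t_name="chr1", t_size=1_000, t_start=0, t_end=20,
            q_name="chrB1", q_size=10_000, q_strand="+", q_start=0, q_end=5_020,
            chain_id="x", blocks=[(10, 0, 5_000), (10, 0, 0)],
        )
        r = map_interval(GenomicInterval("chr1", 0, 20), ChainSet([c]))
        assert r.mapped_ratio == 1.0 and r.target_interval is None

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_per_base_walk(self, trial):
        rng = np.random.default_rng(42 + trial)
        for _ in range(60):
            chain = random_chain(rng)
            cs = ChainSet([chain])
            s = int(rng.integers(0, chain.t_size - 10))
            q = GenomicInterval("chr1", s, s + int(rng.integers(10, 2_000)))
            got = map_interval(q, cs, max_expansion=np.inf)
            assert got.mapped_ratio == pytest.approx(chain_walk_ratio(q, chain))
            targets = chain_walk_targets(q, chain)
            if targets:
                assert got.target_interval.start == min(targets)
                assert got.target_interval.end == max(targets) + 1
            else:
                assert got.target_interval is None

    def test_minus_strand_reflection_equals_plus_strand(self):
        """Mapping through a - strand chain equals the reflected + chain."""
        plus = Chain(
            score=10, t_name="chr1", t_size=1_000, t_start=100, t_end=400,
            q_name="chrB1", q_size=1_000, q_strand="+", q_start=200, q_end=500,
            chain_id="p", blocks=[(100, 50, 50), (150, 0, 0)],
        )
        # same alignment expressed on the reversed target strand
        minus = Chain(
            score=10, t_name="chr1", t_size=1_000, t_start=100, t_end=400,
            q_name="chrB1", q_size=1_000, q_strand="-",
            q_start=1_000 - 500, q_end=1_000 - 200,
            chain_id="m", blocks=[(150, 50, 50), (100, 0, 0)],
        )
        q = GenomicInterval("chr1", 120, 380)
        rp = map_interval(q, ChainSet([plus]))
        rm = map_interval(q, ChainSet([minus]))
        assert rp.mapped_ratio == rm.mapped_ratio
        assert (rm.target_interval.start, rm.target_interval.end) == (
            rp.target_interval.start,
            rp.target_interval.end,
        )


class TestConservationFraction:
    def test_threshold_inclusive(self):
        c = Chain(
            score=10, t_name="chr1", t_size=10_000, t_start=0, t_end=500,
            q_name="chrB1", q_size=10_000, q_strand="+", q_start=0, q_end=500,
            chain_id="1", blocks=[(500, 0, 0)],
        )
        regions = IntervalSet([GenomicInterval("chr1", 0, 1_000)])  # ratio 0.5
        frac, table = conservation_fraction(regions, ChainSet([c]), 0.5)
        assert frac == 1.0 and bool(table["conserved"].iloc[0])
        frac51, _ = conservation_fraction(regions, ChainSet([c]), 0.51)
        assert frac51 == 0.0

    def test_empty_chains_give_zero(self):
        regions = IntervalSet([GenomicInterval("chr1", 0, 100)])
        frac, _ = conservation_fraction(regions, ChainSet([]), 0.5)
        assert frac == 0.0

    def test_empty_set_warns_missing(self):
        with pytest.warns(UserWarning):
            frac, _ = conservation_fraction(IntervalSet(), ChainSet([]), 0.5)
        assert frac is None


class TestThresholdSweep:
    def test_known_per_element_ratios(self):
        # two elements with ratios 0.3 and 0.6
        def partial(start, covered):
            return Chain(
                score=10, t_name="chr1", t_size=100_000, t_start=start,
                t_end=start + covered, q_name="chrB1", q_size=100_000,
                q_strand="+", q_start=start, q_end=start + covered,
                chain_id=f"c{start}", blocks=[(covered, 0, 0)],
            )

        cs = ChainSet([partial(0, 300), partial(10_000, 600)])
        regions = IntervalSet(
            [GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 10_000, 11_000)]
        )
        sweep = threshold_sweep(regions, cs, [0.2, 0.5, 0.99])
        assert list(sweep["fraction_conserved"]) == [1.0, 0.5, 0.0]
        fr = sweep["fraction_conserved"].to_numpy()
        assert np.all(np.diff(fr) <= 0)

    def test_unsorted_ratios_rejected(self):
        with pytest.raises(ValidationError):
            threshold_sweep(IntervalSet(), ChainSet([]), [0.5, 0.2])

    def test_empty_ratio_list(self):
        sweep = threshold_sweep(IntervalSet(), ChainSet([]), [])
        assert len(sweep) == 0
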