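import numpy as np
import pytest

from poisedloop.intervals import GenomicInterval, IntervalSet, TssRecord


def ivset(*triples, genome=None):
    """Shorthand: ivset((\"chr1\", 0, 10), ...) -> IntervalSet."""
    return IntervalSet(
        [GenomicInterval(*t) if isinstance(t, tuple) else t for t in triples],
        genome,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome():
    return {"chr1": 100_000, "chr2": 100_000}


@pytest.fixture
def toy_tss():
    return [
        TssRecord("geneA", "chr1", 6_000, "+"),
        TssRecord("geneB", "chr1", 60_000, "-"),
        TssRecord("geneC", "chr2", 30_000, "+"),
    ]
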