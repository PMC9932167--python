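import numpy as np
import pytest

from th17pipe.core import GeneModel, Interval


@pytest.fixture
def rng():
    return np.random.default_rng(20230216)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("g1", "chr1", 100, 200, "+"),
        GeneModel("g2", "chr1", 500, 900, "-"),
        GeneModel("g3", "chr2", 50, 400, "+"),
    ]


@pytest.fixture
def toy_peaks():
    return [
        Interval("chr1", 150, 250, "p1"),
        Interval("chr1", 850, 950, "p2"),
        Interval("chr2", 400, 500, "p3"),
    ]


def brute_force_overlap(a_chrom, a_start, a_end, b_chrom, b_start, b_end):
    """Quadratic-scan overlap predicate shared by interval oracles."""
    return a_chrom == b_chrom and a_start < b_end and b_start < a_end
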