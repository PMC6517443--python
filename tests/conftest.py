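import numpy as np
import pytest

from linchk.core import GeneAnnotation, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_gene():
    """Two-exon '+' gene on chr1: exons [100,200) and [300,400)."""
    return GeneAnnotation(
        "G1",
        "lincRNA",
        "+",
        [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 300, 400, "+")],
    )


def random_intervals(rng, n, span=100, chrom="chr1"):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 1))
        e = int(rng.integers(s + 1, span + 1))
        out.append(GenomicInterval(chrom, s, e))
    return out
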