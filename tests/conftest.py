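import numpy as np
import pytest

from semethyl.io import Methylome


@pytest.fixture
def tiny_methylome() -> Methylome:
    """8 covered CpGs on one chromosome, mixed levels."""
    pos = [100, 210, 320, 430, 540, 650, 760, 870]
    meth = [1, 0, 2, 9, 10, 8, 1, 0]
    unmeth = [9, 10, 8, 1, 0, 2, 9, 10]
    return Methylome(["chr1"] * 8, pos, meth, unmeth, sample_id="tiny")


def make_methylome(pos, meth, unmeth, chrom="chr1", **kw):
    n = len(pos)
    return Methylome([chrom] * n, pos, meth, unmeth, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
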