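import numpy as np
import pytest

from phylosnv.io import CountMatrices, Locus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_counts(R, V, min_coverage=1, chrom="chr1"):
    R = np.asarray(R)
    n, m = R.shape
    loci = [Locus(chrom, j + 1, "A", "C") for j in range(m)]
    names = [f"cell{i}" for i in range(n)]
    return CountMatrices(R=R, V=np.asarray(V), loci=loci, cell_names=names,
                         min_coverage=min_coverage)


@pytest.fixture
def small_counts():
    R = [[5, 0, 2], [0, 3, 2], [4, 1, 0]]
    V = [[0, 4, 2], [0, 2, 0], [1, 3, 0]]
    return make_counts(R, V)
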