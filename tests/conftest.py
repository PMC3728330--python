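import numpy as np
import pandas as pd
import pytest

from bsaqtl.gprime import COUNT_COLUMNS


def make_counts(chrom, pos, n1, n2, n3, n4):
    """Build a package-standard SNP count table from parallel lists."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "n1_ES": n1,
            "n2_ES": n2,
            "n1_ET": n3,
            "n2_ET": n4,
        }
    )


def random_tables(rng, n, max_depth=200):
    """Random strictly-valid 2x2 count tables (both pools nonzero depth)."""
    d_es = rng.integers(1, max_depth, size=n)
    d_et = rng.integers(1, max_depth, size=n)
    n1 = rng.binomial(d_es, rng.uniform(0.05, 0.95, size=n))
    n3 = rng.binomial(d_et, rng.uniform(0.05, 0.95, size=n))
    return n1, d_es - n1, n3, d_et - n3


@pytest.fixture
def rng():
    return np.random.default_rng(20_2509)


@pytest.fixture
def toy_counts():
    return make_counts(
        ["chr01"] * 3 + ["chr02"] * 2,
        [100, 5000, 9000, 200, 700],
        [30, 60, 50, 40, 55],
        [20, 40, 50, 60, 45],
        [25, 40, 50, 45, 52],
        [30, 60, 50, 55, 48],
    )
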