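import numpy as np
import pytest

from atactf import fixtures
from atactf.genomics_io import ChromSizes, GenomicInterval, IntervalSet


@pytest.fixture(scope="session")
def toy_truth():
    """One deterministic 3-cell-type fixture shared across tests."""
    return fixtures.generate(fixtures.FixtureConfig(seed=7, n_cell_types=3))


@pytest.fixture(scope="session")
def toy_cells(toy_truth):
    return fixtures.build_cell_data(toy_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def chrom_sizes():
    return ChromSizes.from_dict({"chrA": 10_000, "chrB": 5_000})


def make_intervals(chrom, pairs):
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in pairs])
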