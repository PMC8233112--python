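import numpy as np
import pytest

import avanet as an


@pytest.fixture(scope="session")
def critical_raster():
    """Moderate-length critical branching raster shared across test modules."""
    return an.simulate_branching_raster(an.SimConfig(n_bins=100_000, seed=11))


@pytest.fixture(scope="session")
def critical_avalanches(critical_raster):
    return an.segment_avalanches(critical_raster)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sparse_raster(rng, n_electrodes=8, n_bins=400, rate=0.05):
    counts = rng.poisson(rate, size=(n_electrodes, n_bins))
    return an.EventRaster(counts=counts, dt_ms=1.0)


def random_weighted_digraph(rng, n=12, density=0.5, w_lo=0.01, w_hi=1.0):
    w = rng.uniform(w_lo, w_hi, size=(n, n))
    w[rng.random((n, n)) > density] = 0.0
    np.fill_diagonal(w, 0.0)
    return an.WeightedDigraph(weights=w)
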