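import numpy as np
import pytest

from brainrev import TimeSeriesMatrix, WindowingScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_scheme():
    return WindowingScheme(window_length=90, overlap=85)


@pytest.fixture
def noise_ts(rng):
    """5 regions x 200 timepoints of i.i.d. Gaussian noise."""
    return TimeSeriesMatrix(
        tuple(f"r{i}" for i in range(5)), rng.normal(size=(5, 200))
    )


def make_noise_ts(seed, n_regions=5, length=200):
    g = np.random.default_rng(seed)
    return TimeSeriesMatrix(
        tuple(f"r{i}" for i in range(n_regions)),
        g.normal(size=(n_regions, length)),
    )


@pytest.fixture
def directed_pair_ts():
    """Strongly directed 2-region series: x2(t) = x1(t-1) + noise."""
    g = np.random.default_rng(99)
    n = 2000
    x1 = g.normal(size=n + 1)
    x2 = x1[:-1] + g.normal(size=n)
    return TimeSeriesMatrix(("x1", "x2"), np.vstack([x1[1:], x2]))
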