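import numpy as np
import pytest

from pswarp import moonbeam
from pswarp.embed import TimeSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sinusoid_series():
    """Sinusoid sampled at 100 points per period, many periods."""
    n, period = 5000, 100
    t = np.arange(n)
    return TimeSeries(np.sin(2 * np.pi * t / period), sample_rate=100.0)


@pytest.fixture(scope="session")
def noise_series():
    vals = np.random.default_rng(7).standard_normal(100_000)
    return TimeSeries(vals, sample_rate=1.0)


@pytest.fixture(scope="session")
def stationary_run():
    """Constant-parameter (eps = 0) chaotic simulation, noiseless."""
    cfg = moonbeam.default_stationary_config(seed=3, duration=60.0,
                                             noise_sd=0.0)
    return moonbeam.simulate(cfg)


@pytest.fixture(scope="session")
def stationary_series(stationary_run):
    return TimeSeries(stationary_run.measurement,
                      stationary_run.config.sample_rate)
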