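import numpy as np
import pytest

import gaitdtw as g


@pytest.fixture(scope="session")
def s5_template():
    return g.strategy_piecewise()


@pytest.fixture(scope="session")
def default_config():
    return g.DetectorConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Three low-noise trials with the default generative settings."""
    return g.synth_cohort(g.SynthParams(n_trials=3, seed=31))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_series(rng, n):
    """A non-degenerate random series of length n."""
    while True:
        x = rng.normal(size=n)
        if np.std(x) > 1e-6:
            return x
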