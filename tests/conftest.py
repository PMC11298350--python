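import numpy as np
import pytest

from ivjoint.synthetic import (
    NoiseModel,
    SyntheticConfig,
    make_synthetic_spine,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def truth_default():
    """Default synthetic specimen (measurement noise at stated defaults)."""
    return make_synthetic_spine(SyntheticConfig(), seed=1)


@pytest.fixture(scope="session")
def truth_noiseless():
    """Synthetic specimen with zero measurement noise (palpation SD kept)."""
    cfg = SyntheticConfig(noise=NoiseModel(0.0, 0.0, 0.0, 0.0, 2.9))
    return make_synthetic_spine(cfg, seed=1)


@pytest.fixture(scope="session")
def experiment_noiseless(truth_noiseless):
    return simulate_experiment(truth_noiseless, "quasistatic", seed=2)


@pytest.fixture(scope="session")
def experiment_default(truth_default):
    return simulate_experiment(truth_default, "quasistatic", seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
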