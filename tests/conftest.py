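import numpy as np
import pytest

from biasquant import FitConfig, make_scenario, simulate_study


@pytest.fixture(scope="session")
def minimal_scenario():
    return make_scenario("minimal", {"seed": 11})


@pytest.fixture(scope="session")
def minimal_dataset(minimal_scenario):
    return simulate_study(minimal_scenario)


@pytest.fixture(scope="session")
def noiseless_minimal_dataset():
    sc = make_scenario("minimal", {"seed": 11, "noise_sd": 0.0})
    return simulate_study(sc)


@pytest.fixture(scope="session")
def flat_dataset():
    sc = make_scenario("flat_ligand", {"seed": 13})
    return sc, simulate_study(sc)


@pytest.fixture
def fast_fit_config():
    return FitConfig(n_starts=8, seed=5, polish_top=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
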