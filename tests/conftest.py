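import numpy as np
import pytest

from coagsim import AssayConditions, default_population_spec, load_network


@pytest.fixture(scope="session")
def network():
    return load_network()


@pytest.fixture(scope="session")
def conditions():
    return AssayConditions()


@pytest.fixture(scope="session")
def default_profile(network):
    """The cohort-mean individual's randomized levels."""
    return {s.name: s.initial_nM for s in network.species if s.randomized}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec(network):
    return default_population_spec(network, n_individuals=12, seed=7)
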