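import numpy as np
import pytest

from ptmix.synthetic_data import SimulationSpec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-taxon high-signal simulated dataset shared across tests."""
    tree, matrix = simulate(SimulationSpec(n_taxa=10, n_sites=300, seed=7))
    return tree, matrix
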