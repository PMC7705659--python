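import numpy as np
import pytest

from wgdclock.simulate import SimConfig, simulate_genome_pair


@pytest.fixture(scope="session")
def small_config():
    """A compact two-WGD scenario with rate asymmetry, shared across tests."""
    return SimConfig(
        n_genes_ancestor=150,
        n_chromosomes=2,
        loss_rate=0.2,
        rate_asymmetry_r=0.3,
        n_inversions=2,
        n_translocations=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return simulate_genome_pair(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
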