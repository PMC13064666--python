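import numpy as np
import pytest

from evopool.config import SimulationConfig
from evopool.simulate import simulate_ancestor, simulate_experiment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cfg_small():
    """Compact layout exercising every stage in ~1 s."""
    return SimulationConfig(seed=11, genome_length=6_000, n_genes=6,
                            gene_length=300, n_sites=3, n_achips_per_site=3,
                            community_reads=8_000, n_taxa=12)


@pytest.fixture(scope="session")
def ancestor(cfg_small):
    return simulate_ancestor(cfg_small)


@pytest.fixture(scope="session")
def small_experiment(cfg_small):
    return simulate_experiment(cfg_small, keep_reads=True)
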