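import numpy as np
import pytest

from methdyn import build_annotation, build_matrix
from methdyn.synthetic_data import SimConfig, simulate_counts, simulate_genome


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def counts(sim_config, genome):
    return simulate_counts(sim_config, genome)


@pytest.fixture(scope="session")
def matrix(sim_config, counts):
    return build_matrix(counts.sample_sites, sim_config.design, min_cov=5,
                        group_order=list(sim_config.groups))


@pytest.fixture(scope="session")
def annot(genome):
    return build_annotation(genome.sequences, genome.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
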