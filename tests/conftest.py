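import numpy as np
import pytest

from thermosel.synthetic_data import SimulationConfig, gen_genome_and_genes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, n_chromosomes=2, chrom_length=100_000, n_genes=12, n_snps=400
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return gen_genome_and_genes(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
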