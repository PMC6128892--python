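import numpy as np
import pytest

from chromexpress.io_formats import GenomeSpace
from chromexpress.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, small study-shaped simulation used across module tests."""
    return SimulationConfig(
        seed=11,
        n_genes=60,
        chrom_len=360_000,
        spike_chrom_len=120_000,
        n_fragments=20_000,
        n_de_up=6,
        n_de_down=6,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture
def space() -> GenomeSpace:
    return GenomeSpace(chrom_sizes={"chr1": 10_000, "spike_chr1": 5_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
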