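import numpy as np
import pytest

from marktempo.pipeline import run_pipeline
from marktempo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down simulation for unit tests that only need structure."""
    return SimulationConfig(
        seed=42,
        n_promoters=200,
        n_enhancers=40,
        n_background_atac=50,
        n_fragments_per_sample=4000,
    )


@pytest.fixture(scope="session")
def small_ds(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_ds():
    """The default-scale simulation (2,000 promoters, seed 0)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_result(default_ds):
    """Full pipeline run on the default simulation; shared across tests."""
    return run_pipeline(default_ds)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
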