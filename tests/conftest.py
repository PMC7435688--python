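import numpy as np
import pytest

from sterolscreen.simdata import SimulationConfig, simulate_study
from sterolscreen.workflow import run_discovery


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: enough structure for every stage, fast to cluster."""
    return SimulationConfig(
        n_samples=80,
        n_species=12,
        encoder_species=3,
        genes_per_species=4,
        sequencing_depth=5e4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_discovery(small_study):
    return run_discovery(small_study)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
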