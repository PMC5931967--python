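import numpy as np
import pytest

from phagelight.synthetic import SimulationConfig, SyntheticGenomeSpec, simulate_genome


@pytest.fixture
def config():
    return SimulationConfig(seed=1)


@pytest.fixture
def quiet_config():
    """Noise-free configuration: deterministic mean-model outputs."""
    return SimulationConfig(seed=1, noise_cv=0.0, ct_sd=0.0, fvfm_noise_cv=0.0)


@pytest.fixture(scope="session")
def planted_genome():
    """Default synthetic genome with its ground-truth plan (seed 5)."""
    return simulate_genome(SyntheticGenomeSpec(), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
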