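import numpy as np
import pytest

from attenscan import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """A small noise-free genome: 12 genes, planted classes, seed 5."""
    return simulate_genome(SimulationConfig(n_genes=12, rng_seed=5))


@pytest.fixture(scope="session")
def noisy_sim():
    """A 50-gene genome with lognormal track noise and Poisson site counts."""
    return simulate_genome(
        SimulationConfig(noise_model="lognormal", noise_cv=0.2, rng_seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
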