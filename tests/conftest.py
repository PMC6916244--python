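import numpy as np
import pytest

from xylemae.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A short (8 h) experiment, cheap enough for repeated use."""
    return SimulationConfig(
        seed=42,
        total_duration_h=8.0,
        expected_embolisms=60.0,
        background_total=2500.0,
        psi_noise_mpa=0.0,
        psi_every_minutes=30.0,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
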