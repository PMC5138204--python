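import numpy as np
import pytest

from riemerp.simulator import ERPModel, ParadigmConfig, simulate_epochs


def random_spd(rng: np.random.Generator, d: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix: A A.T + d*I, scaled."""
    a = rng.standard_normal((d, d))
    return scale * (a @ a.T + d * np.eye(d))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config() -> ParadigmConfig:
    """Tiny 5-command paradigm: 5 blocks x 5 reps, 8 channels, 256 Hz."""
    return ParadigmConfig(K=5, fs=256, n_channels=8, reps_per_command=5, n_blocks=5)


@pytest.fixture(scope="session")
def small_epochs(small_config):
    """Moderate-SNR epochs under the default ERP model."""
    return simulate_epochs(small_config, ERPModel(), seed=7)


@pytest.fixture(scope="session")
def separable_epochs(small_config):
    """High-SNR epochs: P300 far above the noise floor."""
    erp = ERPModel(p300_amplitude=20.0, noise_sigma=2.0, pink_noise_scale=1.0)
    return simulate_epochs(small_config, erp, seed=11)
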