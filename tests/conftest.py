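import numpy as np
import pytest

from cvepstop.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale geometry: 8 classes, 2 code cycles, 4 channels."""
    return SimConfig(
        n_classes=8, n_reps=6, n_channels=4, n_cycles=2, sigma=0.5, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return simulate_dataset(
        SimConfig(n_classes=8, n_reps=4, n_channels=4, n_cycles=2,
                  sigma=0.0, sigma_bg=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The full study geometry: 36 classes x 3 reps, 4.2 s trials."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
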