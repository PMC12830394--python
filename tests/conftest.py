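import numpy as np
import pytest

from vmre import SimulationConfig, Stage


@pytest.fixture
def noiseless_config():
    """Noise-free generator with a single 4.0 kPa stage level."""
    return SimulationConfig(
        seed=11, snr=np.inf, grid_shape=(16, 16, 16),
        stage_stiffness={s: (4.0, 0.0) for s in Stage},
    )


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
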