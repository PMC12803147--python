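import numpy as np
import pytest

from emgsort import MotorPool, make_force_signal, make_synthetic_basis


@pytest.fixture(scope="session")
def small_basis():
    """3 units on 8 channels with conduction delays, identity whitening."""
    return make_synthetic_basis(3, 8, nt=61, n_pcs=9, max_delay=10, seed=7)


@pytest.fixture(scope="session")
def short_drive():
    """Two seconds of locomotor-like drive at 30 kHz."""
    return make_force_signal(2.0, 30000.0, seed=7, amplitude=8.0)


@pytest.fixture(scope="session")
def small_pool():
    return MotorPool(n_units=3, theta1=2.0, theta2=1.0, sampling_rate=30000.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
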