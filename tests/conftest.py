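import numpy as np
import pytest

from megconsist import Conductor, spiral_sensor_array


@pytest.fixture(scope="session")
def conductor():
    return Conductor()


@pytest.fixture(scope="session")
def sensors(conductor):
    """Small sensor array shared across forward-model tests."""
    return spiral_sensor_array(48, conductor)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
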