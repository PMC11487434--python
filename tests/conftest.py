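import numpy as np
import pytest

from vertrot.io import PointCloud
from vertrot.phantom import PhantomConfig, generate_vertebra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.normal(size=(100, 3)) * 10.0, name="random")


@pytest.fixture
def phantom_12deg():
    """Noiseless phantom with a 12-degree axial rotation."""
    return generate_vertebra(PhantomConfig(theta_deg=12.0, seed=3))


@pytest.fixture
def collinear_10():
    """Ten collinear points at x = 0..9."""
    return np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
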