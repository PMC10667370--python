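import numpy as np
import pytest

from angiosim.dynamics import ModelParams
from angiosim.geometry import SamplingGrid, shape_from_oblateness
from angiosim.simulation import complete_frame, random_unit_vector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def shape07():
    return shape_from_oblateness(0.7)


@pytest.fixture
def grid():
    return SamplingGrid(K=10, L=8)


@pytest.fixture
def params():
    return ModelParams()


def random_frame(rng):
    """Random right-handed orthonormal frame (helper shared across test modules)."""
    return complete_frame(random_unit_vector(rng))
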