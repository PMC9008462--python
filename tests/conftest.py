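import numpy as np
import pytest

from axodyn.camera import CameraModel
from axodyn.motion import AxonPath


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def camera():
    return CameraModel()


@pytest.fixture
def small_camera():
    """Tiny ROI for rendering tests."""
    return CameraModel(roi=(32, 32))


@pytest.fixture
def long_path():
    return AxonPath.straight(5000.0)
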