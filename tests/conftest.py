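import numpy as np
import pytest

from egoflow import flowfield as ff
from egoflow.design import build_ff3d_design
from egoflow.synth_bold import HRFModel


@pytest.fixture(scope="session")
def geometry():
    return ff.default_geometry()


@pytest.fixture(scope="session")
def low_profile(geometry):
    p = ff.SPEED_PROFILES["low"]
    p.calibrated_scale(geometry)  # warm the calibration cache
    return p


@pytest.fixture(scope="session")
def ff3d_design():
    return build_ff3d_design(seed=1)


@pytest.fixture(scope="session")
def hrf():
    return HRFModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
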