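import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coamap.calibration import DEFAULT_CALIBRATION, Calibration

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def calibration():
    return DEFAULT_CALIBRATION


@pytest.fixture
def small_calibration():
    # 320 x 240 px at the default pixel size: quick to render
    return Calibration(DEFAULT_CALIBRATION.pixel_size_um, 320, 240)
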