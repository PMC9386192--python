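import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermentropy.io import PolygonROI, ROIMask, ThermalFrame, rasterize_polygon

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_frame() -> ThermalFrame:
    temps = np.array(
        [
            [30.0, 30.1, 30.2, 30.3, 30.4],
            [30.1, 30.2, 30.3, 30.4, 30.5],
            [30.2, 30.3, 30.4, 30.5, 30.6],
            [31.0, 31.1, 31.2, 31.3, 31.4],
        ]
    )
    return ThermalFrame(temperatures=temps, time_s=30.0, phase="exercise")


@pytest.fixture
def full_mask(small_frame) -> ROIMask:
    return ROIMask(mask=np.ones(small_frame.shape, dtype=bool), label="chest")


@pytest.fixture
def unit_rect():
    """Rectangle (0,0)-(3,3): rasterizes to a 4x4 block of pixel centers."""
    return PolygonROI(vertices=((0, 0), (0, 3), (3, 3), (3, 0)), label="chest")
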