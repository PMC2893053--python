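import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lensmorph import Calibration, LensMask

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cal100():
    return Calibration(100.0)


def make_disk(radius_px: int, pad: int = 4, ppm: float = 100.0) -> LensMask:
    """Rasterized disk mask: pixel centres within radius of the centre pixel."""
    n = 2 * (radius_px + pad) + 1
    c = radius_px + pad
    rr, cc = np.indices((n, n))
    mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2
    return LensMask(mask, Calibration(ppm))


@pytest.fixture
def disk_factory():
    return make_disk
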