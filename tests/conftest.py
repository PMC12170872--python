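import numpy as np
import pytest
from hypothesis import settings

from mitoquant.core import SynthConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def cfg():
    """Default synthetic-data configuration with a fixed seed."""
    return SynthConfig(seed=123)


@pytest.fixture
def cfg_noiseless():
    return SynthConfig(seed=123, gaussian_sd=0.0)


def disk_mask(size: int, radius: float, center=None) -> np.ndarray:
    """Boolean disk used as an analytic 2D fixture."""
    if center is None:
        center = (size // 2, size // 2)
    yy, xx = np.mgrid[:size, :size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
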