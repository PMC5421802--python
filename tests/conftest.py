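import numpy as np
import pytest

from ctcflow.amplicon_library import PrimerDesign
from ctcflow.enumeration import GateConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def design() -> PrimerDesign:
    return PrimerDesign()


@pytest.fixture
def gates() -> GateConfig:
    return GateConfig(ck_epcam_positive_threshold=50.0, cd45_positive_threshold=50.0)


def rasterize_disk(radius: int, pad: int = 2) -> np.ndarray:
    """Pixel-symmetric disk mask used as a shape oracle."""
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
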