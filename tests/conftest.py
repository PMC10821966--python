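import numpy as np
import pytest

from fistulomics.imaging_core import VOIMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_grid(rng):
    """A small textured CT-like grid with anisotropic spacing."""
    return VolumeGrid(rng.normal(40.0, 60.0, size=(10, 11, 12)), (1.152, 1.152, 3.0))


@pytest.fixture
def box_mask():
    """A solid 5x5x5 box inside a 10x11x12 lattice."""
    ind = np.zeros((10, 11, 12), dtype=bool)
    ind[2:7, 3:8, 4:9] = True
    return VOIMask(ind, "ESO")


def make_mask(shape, where) -> VOIMask:
    ind = np.zeros(shape, dtype=bool)
    ind[where] = True
    return VOIMask(ind)
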