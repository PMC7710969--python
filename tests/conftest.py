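import numpy as np
import pytest

from stimconn.images import BoldImage, default_affine


@pytest.fixture
def rng():
    return np.random.default_rng(20201119)


@pytest.fixture
def small_bold(rng):
    """Random 6x5x4 BOLD image on a 4-mm grid, 30 volumes."""
    shape = (6, 5, 4)
    data = rng.standard_normal((*shape, 30)) + 100.0
    return BoldImage(data, tr_seconds=2.0, affine=default_affine(4.0, shape))


def make_bold(data, voxel_mm=4.0, tr=2.0):
    data = np.asarray(data, float)
    return BoldImage(data, tr_seconds=tr, affine=default_affine(voxel_mm, data.shape[:3]))
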