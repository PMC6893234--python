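import numpy as np
import pytest

from diametric.io import BoldRun, SpatialGrid, VolumeMask, default_grid


@pytest.fixture
def grid8() -> SpatialGrid:
    return default_grid((8, 8, 8), voxel_mm=4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def make_run(grid8):
    """Factory for small runs with caller-supplied voxel data or noise."""

    def _make(data=None, tr=2.0, n_volumes=64, seed=0):
        if data is None:
            g = np.random.default_rng(seed)
            data = g.standard_normal(grid8.shape + (n_volumes,))
        return BoldRun(grid8, data, tr)

    return _make


@pytest.fixture
def cube_mask(grid8):
    """Factory for rectangular masks on the 8^3 grid."""

    def _make(lo=(2, 2, 2), hi=(5, 5, 5)):
        vox = np.zeros(grid8.shape, dtype=bool)
        vox[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        return VolumeMask(grid8, vox)

    return _make
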