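import numpy as np
import pytest

from alffpipe import BrainMask, VoxelGrid


@pytest.fixture
def grid():
    return VoxelGrid.isotropic((10, 10, 8), 3.0)


@pytest.fixture
def full_mask(grid):
    return BrainMask(grid, np.ones(grid.shape, dtype=bool))


def flat_mask(grid: VoxelGrid, flat_indices) -> BrainMask:
    """Mask with the given linear voxel indices set, for hand-counted cases."""
    m = np.zeros(int(np.prod(grid.shape)), dtype=bool)
    m[np.asarray(flat_indices)] = True
    return BrainMask(grid, m.reshape(grid.shape))
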