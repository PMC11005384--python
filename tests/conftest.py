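import numpy as np
import pytest

from fapothole.synthetic import CohortSpec
from fapothole.volume_io import FAVolume, MaskVolume, VoxelGrid


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid(shape=(8, 8, 8), voxel_size=(2.0, 2.0, 2.0),
                     orientation_tag="test")


@pytest.fixture
def small_spec(small_grid) -> CohortSpec:
    return CohortSpec(n_control=6, n_mtbi=2, n_mstbi=2,
                      grid=VoxelGrid(shape=(16, 16, 16),
                                     voxel_size=(2.0, 2.04, 3.0),
                                     orientation_tag="test"),
                      noise_sd=0.05, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)


def constant_volume(grid: VoxelGrid, value: float) -> FAVolume:
    return FAVolume(grid=grid, values=np.full(grid.shape, value))


def full_mask(grid: VoxelGrid) -> MaskVolume:
    return MaskVolume(grid=grid, values=np.ones(grid.shape, dtype=bool))
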