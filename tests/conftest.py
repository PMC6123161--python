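import numpy as np
import pytest

from irv4d.grid import ContourMask, DisplacementField, Grid, PhaseVolume
from irv4d.synthetic import PhantomConfig, generate_phantom


def make_sphere_mask(grid: Grid, center_mm, radius_mm, **tags) -> ContourMask:
    x, y, z = grid.meshgrid_mm()
    r2 = ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
          + (z - center_mm[2]) ** 2)
    return ContourMask(r2 <= radius_mm ** 2, grid, **tags)


def make_blob_volume(grid: Grid, center_mm, sigma_mm=18.0, amp=1000.0,
                     phase_index=0) -> PhaseVolume:
    x, y, z = grid.meshgrid_mm()
    r2 = ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
          + (z - center_mm[2]) ** 2)
    return PhaseVolume(amp * np.exp(-r2 / (2 * sigma_mm ** 2)), grid,
                       phase_index=phase_index)


def uniform_shift_field(grid: Grid, shift_mm) -> DisplacementField:
    vec = np.zeros(grid.shape + (3,), dtype=np.float32)
    for a in range(3):
        vec[..., a] = shift_mm[a]
    return DisplacementField(vec, grid)


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """A fast phantom: 32x32x24 voxels, coarse spacing, full organ set.

    Amplitudes avoid organ shifts that land exactly on half a slice, where
    the inclusive 0.5 warp threshold adds a one-voxel shell by convention.
    """
    return PhantomConfig(grid_shape=(32, 32, 24), spacing_mm=(4.0, 4.0, 6.0),
                         diaphragm_amplitude_right_mm=15.5,
                         diaphragm_amplitude_left_mm=16.5, seed=11)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return generate_phantom(tiny_config)


@pytest.fixture(scope="session")
def small_phantom():
    """Mid-size phantom used by registration-quality and IRV tests."""
    cfg = PhantomConfig(grid_shape=(64, 64, 64), spacing_mm=(2.0, 2.0, 3.0),
                        seed=5)
    return generate_phantom(cfg)
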