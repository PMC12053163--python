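import numpy as np
import pytest

from gliogrowth.volume_io import TemplateGrid, Volume


@pytest.fixture
def small_grid() -> TemplateGrid:
    """Desk-scale isotropic grid, origin chosen so world x=0 is mid-grid."""
    return TemplateGrid.from_origin((40, 40, 40), (1.0, 1.0, 1.0),
                                    (-19.5, -19.5, -19.5))


def ball_volume(grid: TemplateGrid, center_vox, radius: float) -> Volume:
    """Voxelized ball: voxels whose center is within `radius` of `center_vox`."""
    ii, jj, kk = np.indices(grid.shape)
    d2 = ((ii - center_vox[0]) ** 2 + (jj - center_vox[1]) ** 2
          + (kk - center_vox[2]) ** 2)
    return Volume(grid, (d2 <= radius ** 2).astype(np.uint8), "mask")


@pytest.fixture
def ball_factory():
    return ball_volume
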