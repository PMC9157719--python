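import numpy as np
import pytest

from dtpradiomics.discretize import DiscretizedROI
from dtpradiomics.io import SUVVolume


def random_roi(rng, max_side=6, n_levels=4) -> DiscretizedROI:
    """A random small discretized ROI with a random (nonempty) mask."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int64)
    levels[~mask] = 0
    return DiscretizedROI(
        levels=levels, mask=mask, n_levels=n_levels, voxel_size_mm=(1.0, 1.0, 1.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def ball_volume(
    radius_mm=20.0,
    inside_suv=8.0,
    background_suv=1.0,
    voxel_mm=4.0,
    shape=(32, 32, 32),
    center_vox=None,
) -> SUVVolume:
    """A hard-edged digitized ball on a uniform background."""
    if center_vox is None:
        center_vox = tuple(s / 2 for s in shape)
    idx = np.indices(shape)
    d2 = sum((idx[a] + 0.5 - center_vox[a]) ** 2 for a in range(3)) * voxel_mm**2
    values = np.where(d2 <= radius_mm**2, inside_suv, background_suv)
    return SUVVolume(values=values, voxel_size_mm=(voxel_mm,) * 3)
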