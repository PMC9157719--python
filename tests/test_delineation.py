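"""SUVpeak, isocontour delineation, background shell, qualification filter."""

import numpy as np
import pytest
from oracles import sphere_mask_offsets

from conftest import ball_volume
from dtpradiomics.delineation import (
    SeedRegion,
    background_shell_mean,
    delineate_contrast,
    delineate_threshold,
    suv_peak,
)
from dtpradiomics.io import SUVVolume
from scipy import ndimage


def seed_for(volume, pad=0):
    return SeedRegion(bbox=np.array([[0, s] for s in volume.shape]))


class TestSUVPeak:
    def test_constant_field(self):
        vol = SUVVolume(np.full((8, 8, 8), 5.0), (4.0,) * 3)
        assert suv_peak(vol, seed_for(vol)) == pytest.approx(5.0)

    def test_single_hot_voxel_enumeration(self):
        """One hot 4 mm voxel: the 1 mL sphere mean equals hot/|sphere|."""
        values = np.zeros((9, 9, 9))
        values[4, 4, 4] = 100.0
        vol = SUVVolume(values, (4.0,) * 3)
        radius = (3 * 1000 / (4 * np.pi)) ** (1 / 3)
        offsets = sphere_mask_offsets((4.0,) * 3, radius)
        expected = 100.0 / len(offsets)
        got = suv_peak(vol, seed_for(vol))
        assert got == pytest.approx(expected)
        assert got < values.max()  # peak is a sphere mean, below the voxel max

    def test_whole_voxel_translation_equivariance(self):
        base = np.zeros((12, 12, 12))
        base[4:7, 4:7, 4:7] = 9.0
        vol1 = SUVVolume(base, (4.0,) * 3)
        vol2 = SUVVolume(np.roll(base, (2, 1, 0), axis=(0, 1, 2)), (4.0,) * 3)
        assert suv_peak(vol1, seed_for(vol1)) == pytest.approx(
            suv_peak(vol2, seed_for(vol2))
        )

    def test_clipped_sphere_warns(self):
        values = np.zeros((6, 6, 6))
        values[0, 0, 0] = 50.0
        vol = SUVVolume(values, (4.0,) * 3)
        with pytest.warns(UserWarning, match="clipped"):
            suv_peak(vol, SeedRegion(bbox=np.array([[0, 1], [0, 1], [0, 1]])))


class TestThresholdDelineation:
    def test_pct40_threshold_definition(self):
        vol = ball_volume(inside_suv=10.0, background_suv=1.0)
        res = delineate_threshold(vol, seed_for(vol), "PCT40")
        assert res.threshold_used == pytest.approx(4.0)
        assert vol.values[res.mask.mask].min() >= res.threshold_used

    def test_suv4_separable_levels(self):
        vol = ball_volume(inside_suv=5.0, background_suv=1.0)
        res = delineate_threshold(vol, seed_for(vol), "SUV4")
        expected = vol.values >= 5.0
        np.testing.assert_array_equal(res.mask.mask, expected)

    def test_suv4_below_threshold_degenerate(self):
        vol = ball_volume(inside_suv=3.5, background_suv=1.0)
        res = delineate_threshold(vol, seed_for(vol), "SUV4")
        assert res.mask.n_voxels == 0
        assert not res.qualifies

    def test_threshold_monotonicity(self):
        """Raising the threshold never adds voxels."""
        rng = np.random.default_rng(7)
        values = ndimage.gaussian_filter(rng.uniform(0, 10, (12, 12, 12)), 1.0)
        values[6, 6, 6] = 12.0
        vol = SUVVolume(values, (4.0,) * 3)
        seed = seed_for(vol)
        from dtpradiomics.delineation import _component_mask

        prev = None
        for thr in (2.0, 4.0, 6.0, 8.0):
            mask = _component_mask(vol, seed, thr)
            if prev is not None:
                assert np.all(mask <= prev)
            prev = mask

    def test_mask_single_connected_component(self):
        """Two separated hot balls: only the seeded one is kept."""
        values = np.ones((24, 24, 24))
        values[3:7, 3:7, 3:7] = 8.0
        values[16:20, 16:20, 16:20] = 8.0
        vol = SUVVolume(values, (4.0,) * 3)
        seed = SeedRegion(bbox=np.array([[2, 8], [2, 8], [2, 8]]))
        res = delineate_threshold(vol, seed, "PCT40")
        labels, n = ndimage.label(res.mask.mask, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert not res.mask.mask[16:20, 16:20, 16:20].any()

    def test_qualification_is_64_voxels(self):
        values = np.ones((12, 12, 12))
        values[2:6, 2:6, 2:6] = 10.0  # exactly 64 hot voxels
        vol = SUVVolume(values, (4.0,) * 3)
        res = delineate_threshold(vol, seed_for(vol), "PCT40")
        assert res.mask.n_voxels == 64 and res.qualifies
        values[2, 2, 2] = 1.0  # 63 voxels
        res63 = delineate_threshold(
            SUVVolume(values, (4.0,) * 3), seed_for(vol), "PCT40"
        )
        assert res63.mask.n_voxels == 63 and not res63.qualifies


class TestBackgroundShell:
    def test_uniform_background(self):
        vol = ball_volume(radius_mm=12, inside_suv=8.0, background_suv=1.0,
                          shape=(40, 40, 40))
        assert background_shell_mean(vol, seed_for(vol)) == pytest.approx(1.0)

    def test_hot_voxels_excluded(self):
        """Shell voxels above SUV 4 are excluded from the background mean."""
        vol = ball_volume(radius_mm=12, inside_suv=8.0, background_suv=1.0,
                          shape=(40, 40, 40))
        values = vol.values.copy()
        # paint half of the far-field at SUV 5 (will fall inside the shell too)
        values[:, :, :8][values[:, :, :8] == 1.0] = 5.0
        vol2 = SUVVolume(values, vol.voxel_size_mm)
        assert background_shell_mean(vol2, seed_for(vol2)) == pytest.approx(1.0)

    def test_shell_matches_pairwise_distance_oracle(self):
        """EDT shell equals brute-force nearest-voxel distances."""
        vol = ball_volume(radius_mm=10, inside_suv=8.0, background_suv=1.0,
                          shape=(24, 24, 24))
        smax = vol.values.max()
        core = vol.values >= 0.7 * smax
        core_pts = np.argwhere(core) * 4.0
        pts = np.stack(np.indices(vol.shape), axis=-1).reshape(-1, 3) * 4.0
        d = np.sqrt(
            ((pts[:, None, :] - core_pts[None, :, :]) ** 2).sum(-1)
        ).min(1).reshape(vol.shape)
        expected = (d >= 20.0) & (d < 24.0) & (vol.values <= 4.0)
        got_mean = background_shell_mean(vol, seed_for(vol))
        assert got_mean == pytest.approx(vol.values[expected].mean())

    def test_empty_shell_is_an_error(self):
        vol = ball_volume(radius_mm=10, inside_suv=8.0, background_suv=1.0,
                          shape=(8, 8, 8))  # grid too small for a 2 cm shell
        with pytest.raises(ValueError, match="background"):
            background_shell_mean(vol, seed_for(vol))


class TestContrastDelineation:
    def test_threshold_arithmetic(self):
        vol = ball_volume(radius_mm=16, inside_suv=8.0, background_suv=1.0,
                          shape=(40, 40, 40))
        res = delineate_contrast(vol, seed_for(vol))
        assert res.suv_peak == pytest.approx(8.0)
        assert res.background_suv == pytest.approx(1.0)
        assert res.threshold_used == pytest.approx(5.0)
        assert vol.values[res.mask.mask].min() >= 5.0

    def test_threshold_scales_with_peak_at_zero_background(self):
        vol = ball_volume(radius_mm=16, inside_suv=8.0, background_suv=1e-9,
                          shape=(40, 40, 40))
        res1 = delineate_contrast(vol, seed_for(vol))
        vol2 = SUVVolume(vol.values * 2, vol.voxel_size_mm)
        res2 = delineate_contrast(vol2, seed_for(vol2))
        assert res2.threshold_used == pytest.approx(2 * res1.threshold_used, rel=1e-6)
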