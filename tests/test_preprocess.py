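import numpy as np
import pytest

import oracles
from conftest import small_config
from ezdetect import preprocess
from ezdetect.preprocess import (
    BilateralParams,
    GraphSearchParams,
    _dp_path,
    bilateral_filter_volume,
    extract_voi,
    flatten,
    flatten_shifts,
    segment_surfaces,
    shift_mask,
    smooth_surfaces_tps,
)
from ezdetect.synthetic_oct import generate_phantom
from ezdetect.volume_model import OCTVolume, SurfaceSet, VoxelMask


def _vol(arr):
    return OCTVolume(np.asarray(arr, dtype=float), (1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# bilateral filtering
# ---------------------------------------------------------------------------

class TestBilateral:
    def test_constant_slice_unchanged(self):
        vol = _vol(np.full((6, 2, 7), 3.5))
        out = bilateral_filter_volume(vol, BilateralParams())
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_large_sigma_range_approaches_gaussian(self, rng):
        from scipy.ndimage import gaussian_filter

        img = rng.uniform(0, 1, (9, 9))
        vol = OCTVolume(img[:, None, :], (1, 1, 1))
        p = BilateralParams(sigma_spatial=2.0, sigma_range=1e6)
        out = bilateral_filter_volume(vol, p).intensities[:, 0, :]
        num = gaussian_filter(img, 2.0, mode="constant")
        den = gaussian_filter(np.ones_like(img), 2.0, mode="constant")
        np.testing.assert_allclose(out, num / den, rtol=1e-3)

    def test_matches_direct_bilateral_within_two_percent(self, rng):
        p = BilateralParams()
        for _ in range(5):
            img = rng.uniform(0, 1, (5, 5))
            got = bilateral_filter_volume(
                OCTVolume(img[:, None, :], (1, 1, 1)), p
            ).intensities[:, 0, :]
            want = oracles.bilateral_direct(img, p.sigma_spatial,
                                            0.1 * (img.max() - img.min()))
            assert abs(got[2, 2] - want[2, 2]) <= 0.02 * abs(want[2, 2])

    def test_single_bright_pixel_centre_matches_oracle(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        got = bilateral_filter_volume(
            OCTVolume(img[:, None, :], (1, 1, 1)), BilateralParams()
        ).intensities[2, 0, 2]
        want = oracles.bilateral_direct(img, 3.0, 0.1)[2, 2]
        assert got == pytest.approx(want, rel=0.02)

    def test_never_widens_slice_range(self, rng):
        arr = rng.uniform(-4, 7, (12, 3, 16))
        out = bilateral_filter_volume(_vol(arr), BilateralParams()).intensities
        for y in range(3):
            assert out[:, y, :].min() >= arr[:, y, :].min() - 1e-12
            assert out[:, y, :].max() <= arr[:, y, :].max() + 1e-12

    def test_non_finite_input_rejected(self):
        arr = np.zeros((3, 2, 3))
        vol = _vol(arr)
        vol.intensities[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            bilateral_filter_volume(vol, BilateralParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BilateralParams(sigma_spatial=0)
        with pytest.raises(ValueError):
            BilateralParams(spatial_factor=0)


# ---------------------------------------------------------------------------
# surface segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_dp_equals_exhaustive_search(self, rng):
        """Column DP achieves exactly the brute-force optimal path cost."""
        for _ in range(5):
            cost = rng.normal(size=(7, 16))
            lo = np.full(7, 1)
            hi = np.full(7, 14)
            _, total = _dp_path(cost, lo, hi, bound=1)
            best = oracles.dp_path_direct(cost, lo, hi, bound=1)
            assert total == pytest.approx(best, abs=1e-10)

    def test_noise_free_phantom_recovered_within_one_voxel(self, clean_phantom):
        vol, truth = clean_phantom
        surf = segment_surfaces(vol)
        assert surf.z_of.shape[0] == 11
        err = np.abs(surf.z_of - truth.surfaces.z_of)
        assert err.max() <= 1.0

    def test_noisy_phantom_surfaces_ordered_everywhere(self, noisy_phantom):
        vol, _ = noisy_phantom
        den = bilateral_filter_volume(vol)
        surf = segment_surfaces(den)
        assert np.all(np.diff(surf.z_of, axis=0) >= 0)

    def test_infeasible_separation_named(self, clean_phantom):
        vol, _ = clean_phantom
        with pytest.raises(ValueError, match="min_separation"):
            segment_surfaces(vol, GraphSearchParams(min_separation=30))


# ---------------------------------------------------------------------------
# thin-plate-spline smoothing
# ---------------------------------------------------------------------------

class TestTps:
    def _planes(self):
        x = np.arange(32)[:, None]
        y = np.arange(12)[None, :]
        base = 10.0 + 0.1 * x + 0.2 * y
        return SurfaceSet(np.stack([base + 3 * s for s in range(11)]))

    def test_planar_surfaces_reproduced(self):
        s = self._planes()
        out = smooth_surfaces_tps(s, regularization=0.0)
        np.testing.assert_allclose(out.z_of, s.z_of, atol=1e-6)

    def test_huge_regularization_tends_to_best_fit_plane(self, rng):
        s = self._planes()
        s.z_of[5] += rng.normal(0, 0.5, size=s.z_of[5].shape)
        out = smooth_surfaces_tps(s, regularization=1e9)
        surf = out.z_of[5]
        # a plane has zero second differences
        assert np.abs(np.diff(surf, n=2, axis=0)).max() < 1e-4
        assert np.abs(np.diff(surf, n=2, axis=1)).max() < 1e-4

    def test_smoothing_reduces_noise_on_sinusoid(self, rng):
        x = np.arange(64)[:, None]
        y = np.arange(16)[None, :]
        true = 30 + 3 * np.sin(2 * np.pi * x / 64) + 2 * np.cos(2 * np.pi * y / 16)
        noisy = true + rng.normal(0, 1.0, size=(64, 16))
        stack = np.stack([noisy + 3 * s for s in range(11)])
        out = smooth_surfaces_tps(SurfaceSet(np.sort(stack, axis=0)))
        rms_before = np.sqrt(np.mean((noisy - true) ** 2))
        rms_after = np.sqrt(np.mean((out.z_of[0] - true) ** 2))
        assert rms_after < rms_before


# ---------------------------------------------------------------------------
# flattening and VOI
# ---------------------------------------------------------------------------

class TestFlatten:
    def test_surface11_constant_after_flattening(self, noisy_phantom):
        vol, truth = noisy_phantom
        flat_vol, flat_surf = flatten(vol, truth.surfaces)
        from ezdetect.volume_model import round_half_deep

        z11 = round_half_deep(flat_surf.z_of[10])
        assert np.unique(z11).size == 1
        assert flat_vol.shape == vol.shape

    def test_flatten_is_idempotent(self, noisy_phantom):
        vol, truth = noisy_phantom
        v1, s1 = flatten(vol, truth.surfaces)
        assert np.all(flatten_shifts(s1) == 0)
        v2, s2 = flatten(v1, s1)
        np.testing.assert_array_equal(v2.intensities, v1.intensities)

    def test_shift_mask_consistent_with_volume_shift(self, noisy_phantom):
        vol, truth = noisy_phantom
        sh = flatten_shifts(truth.surfaces)
        moved = shift_mask(truth.disruption_mask, sh)
        # voxel count preserved where shifts stay in range (interior blobs)
        assert moved.count() == truth.disruption_mask.count()
        flat_vol, flat_surf = flatten(vol, truth.surfaces)
        voi = extract_voi(flat_vol, flat_surf)
        assert np.all(voi.values[moved.values])


class TestVoi:
    def test_half_open_interval_definition(self):
        z = np.concatenate(
            [np.tile([[2.0]], (1, 1, 1)) + s for s in range(7)],
        )
        z_of = np.zeros((11, 1, 1))
        z_of[:7] = np.arange(7).reshape(-1, 1, 1)
        z_of[6] = 10.0
        z_of[7] = 14.0
        z_of[8:] = 15.0
        vol = _vol(np.zeros((1, 1, 20)))
        voi = extract_voi(vol, SurfaceSet(z_of))
        assert sorted(np.nonzero(voi.values[0, 0])[0]) == [10, 11, 12, 13]

    def test_degenerate_column_keeps_one_voxel(self):
        z_of = np.tile(np.linspace(2, 12, 11)[:, None, None], (1, 2, 2))
        z_of[7] = z_of[6]  # surfaces 7 and 8 coincide
        z_of[8:] = 13.0
        voi = extract_voi(_vol(np.zeros((2, 2, 20))), SurfaceSet(np.sort(z_of, axis=0)))
        assert np.all(voi.values.sum(axis=2) == 1)

    def test_ground_truth_disruption_inside_voi_with_true_surfaces(self, noisy_phantom):
        vol, truth = noisy_phantom
        voi = extract_voi(vol, truth.surfaces)
        assert np.all(voi.values[truth.disruption_mask.values])

    def test_voi_volume_matches_surface_gap_arithmetic(self, noisy_phantom):
        vol, truth = noisy_phantom
        voi = extract_voi(vol, truth.surfaces)
        dx, dy, dz = vol.voxel_size_um
        expected = (truth.surfaces.z_of[7] - truth.surfaces.z_of[6]).sum() \
            * dx * dy * dz * 1e-9
        got = voi.count() * dx * dy * dz * 1e-9
        one_layer = vol.nx * vol.ny * dx * dy * dz * 1e-9
        assert abs(got - expected) <= one_layer
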