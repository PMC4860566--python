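import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from ezdetect import features as F
from ezdetect.volume_model import OCTVolume, VoxelMask


class TestDirections:
    def test_axis_aligned_angle_pairs(self):
        offs = F.direction_offsets()
        assert offs[0] == (1, 0, 0)   # (alpha1, alpha2) = (0, 90deg)
        assert offs[8] == (0, 0, 1)   # (0, 0) is the pure-z direction
        assert offs[1] == (1, 1, 0)   # (45, 90)
        assert offs[12] == (1, -1, 1)  # the completing 13th half-axis

    def test_thirteen_unique_non_antiparallel_offsets(self):
        offs = F.direction_offsets()
        assert len(offs) == 13
        assert len(set(offs)) == 13
        for i, a in enumerate(offs):
            for b in offs[i + 1:]:
                assert a != b
                assert a != tuple(-c for c in b)
        # together with negations they cover the full 26-neighbourhood
        full = set(offs) | {tuple(-c for c in o) for o in offs}
        assert len(full) == 26


class TestElementaryFeatures:
    def test_min_max_normalization(self):
        np.testing.assert_allclose(
            F.normalize_intensity([10, 20, 30]), [0, 0.5, 1.0]
        )
        assert np.all(F.normalize_intensity([7, 7, 7]) == 0)

    def test_normalization_affine_invariant(self, rng):
        v = rng.uniform(0, 5, 20)
        np.testing.assert_allclose(
            F.normalize_intensity(v), F.normalize_intensity(3.2 * v - 7.0),
            atol=1e-12,
        )

    def test_block_stats_constant_and_bernoulli(self):
        arr = np.full((5, 5, 5), 0.5)
        assert F.block_stats(arr, (2, 2, 2)) == (0.5, 0.0)
        arr = np.zeros((5, 5, 4))
        arr[..., :2] = 1.0  # half ones, half zeros
        m, s = F.block_stats(arr, (2, 2, 1))
        assert (m, s) == (0.5, 0.5)

    def test_block_stats_matches_triple_loop(self, rng):
        arr = rng.uniform(size=(7, 7, 7))
        for c in [(3, 3, 3), (0, 0, 0), (6, 2, 5)]:
            want = oracles.block_stats_direct(arr, c)
            got = F.block_stats(arr, c)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_abs_diff_zero_on_constant_volume(self):
        arr = np.full((6, 6, 6), 2.0)
        assert F.abs_diff_feature(arr, (3, 3, 3), 1) == 0.0
        assert F.abs_diff_feature(arr, (3, 3, 3), 2) == 0.0

    def test_abs_diff_isolated_bright_voxel(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 1.0
        assert F.abs_diff_feature(arr, (2, 2, 2), 1) == pytest.approx(1.0)

    def test_abs_diff_matches_enumeration(self, rng):
        arr = rng.uniform(size=(6, 6, 6))
        for c in [(0, 0, 0), (3, 2, 4), (5, 5, 5)]:
            for step in (1, 2):
                want = 0.0
                for d in F.direction_offsets():
                    nb = tuple(
                        int(np.clip(ci + step * di, 0, 5)) for ci, di in zip(c, d)
                    )
                    want += abs(arr[c] - arr[nb])
                want /= 13
                assert F.abs_diff_feature(arr, c, step) == pytest.approx(want)


class TestGlcm:
    def test_three_voxel_line_example(self):
        p = F.glcm(np.array([0, 1, 1]).reshape(3, 1, 1), (1, 0, 0), 2)
        np.testing.assert_allclose(p, [[0, 0.25], [0.25, 0.5]])

    def test_props_of_line_example(self):
        p = np.array([[0, 0.25], [0.25, 0.5]])
        contrast, corr, energy, homog = F.glcm_props(p)
        assert contrast == pytest.approx(0.5)
        assert homog == pytest.approx(0.75)
        assert energy == pytest.approx(0.375)
        assert corr == pytest.approx(-1 / 3)

    def test_constant_block_degenerate_conventions(self):
        p = F.glcm(np.full((3, 3, 3), 2), (0, 0, 1), 4)
        assert p[2, 2] == 1.0 and p.sum() == 1.0
        assert F.glcm_props(p) == (0.0, 0.0, 1.0, 1.0)

    def test_uniform_glcm_energy_closed_form(self):
        n = 4
        p = np.full((n, n), 1 / n**2)
        _, _, energy, _ = F.glcm_props(p)
        assert energy == pytest.approx(1 / n**2)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            F.glcm_props(np.ones((3, 3)))

    def test_matches_pair_enumeration(self, rng):
        block = rng.integers(0, 8, size=(5, 5, 5))
        for d in F.direction_offsets():
            got = F.glcm(block, d, 8)
            want = oracles.glcm_direct(block, d, 8)
            np.testing.assert_allclose(got, want, atol=1e-12)
            assert abs(got.sum() - 1) < 1e-12
            np.testing.assert_allclose(got, got.T, atol=0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hnp.arrays(np.int64, (4, 4, 4), elements=st.integers(0, 7)))
    def test_props_bounds(self, block):
        """Energy/homogeneity in (0,1], contrast >= 0, |correlation| <= 1."""
        for d in ((1, 0, 0), (1, -1, 1)):
            contrast, corr, energy, homog = F.glcm_props(F.glcm(block, d, 8))
            assert 0 < energy <= 1 + 1e-12
            assert 0 < homog <= 1 + 1e-12
            assert contrast >= 0
            assert abs(corr) <= 1 + 1e-12


class TestExtractFeatures:
    def _phantom_matrix(self, rng, shape=(9, 9, 9)):
        I = rng.uniform(0, 100, shape)
        voi = np.zeros(shape, bool)
        voi[:, :, 3:6] = True
        vol = OCTVolume(I, (1, 1, 1))
        return I, voi, F.extract_features(vol, VoxelMask(voi))

    def test_descriptor_has_57_columns_in_table_order(self, rng):
        _, _, fm = self._phantom_matrix(rng)
        assert fm.values.shape[1] == 57
        assert fm.columns[0] == "f01_norm_intensity"
        assert fm.columns[5] == "f06_glcm_contrast_d00"
        assert fm.columns[18] == "f19_glcm_correlation_d00"
        assert fm.columns[31] == "f32_glcm_energy_d00"
        assert fm.columns[44] == "f45_glcm_homogeneity_d00"

    def test_matches_per_voxel_oracle_composition(self, rng):
        """Rows equal independent per-feature brute-force recomputation."""
        I, voi, fm = self._phantom_matrix(rng)
        for c in [(0, 0, 3), (4, 4, 4), (8, 8, 5), (2, 7, 3)]:
            i = int(np.flatnonzero((fm.voxel_indices == np.array(c)).all(1))[0])
            want = oracles.feature_row_direct(I, voi, c)
            np.testing.assert_allclose(fm.values[i], want, atol=1e-10)

    def test_constant_voi_degenerate_columns(self):
        I = np.zeros((6, 6, 6))
        voi = np.zeros((6, 6, 6), bool)
        voi[:, :, 2:4] = True
        fm = F.extract_features(OCTVolume(I, (1, 1, 1)), VoxelMask(voi))
        assert np.all(fm.values[:, 5:18] == 0)    # contrast
        assert np.all(fm.values[:, 31:44] == 1)   # energy
        assert np.all(fm.values[:, 44:] == 1)     # homogeneity

    def test_empty_voi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            F.extract_features(
                OCTVolume(np.zeros((3, 3, 3)), (1, 1, 1)),
                VoxelMask(np.zeros((3, 3, 3), bool)),
            )

    def test_feature_invariants_hold_on_noisy_phantom(self, noisy_phantom):
        from ezdetect.preprocess import extract_voi, flatten

        vol, truth = noisy_phantom
        fvol, fsurf = flatten(vol, truth.surfaces)
        voi = extract_voi(fvol, fsurf)
        fm = F.extract_features(fvol, voi)
        assert np.all(np.isfinite(fm.values))
        assert np.all(fm.values[:, 0] >= 0) and np.all(fm.values[:, 0] <= 1)
        assert np.all(fm.values[:, 31:44] > 0) and np.all(fm.values[:, 31:44] <= 1)
        assert np.all(fm.values[:, 44:] > 0) and np.all(fm.values[:, 44:] <= 1 + 1e-12)
        assert np.all(np.abs(fm.values[:, 18:31]) <= 1 + 1e-12)


def _structured(rng, n, rank=8, noise=1e-3):
    """Correlated 57-dim data whose top-10 components carry ~all variance."""
    return rng.normal(size=(n, rank)) @ rng.normal(size=(rank, 57)) \
        + noise * rng.normal(size=(n, 57))


class TestPca:
    def test_ten_components_and_orthonormality(self, rng):
        X = _structured(rng, 200)
        m = F.fit_pca(X)
        assert m.n_components == 10
        np.testing.assert_allclose(m.components @ m.components.T, np.eye(10),
                                   atol=1e-10)
        Z = F.apply_pca(m, X)
        assert Z.shape == (200, 10)

    def test_projected_training_columns_uncorrelated(self, rng):
        X = _structured(rng, 300) * rng.uniform(0.1, 10, 57)
        Z = F.apply_pca(F.fit_pca(X), X)
        cov = np.cov(Z.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_rank_deficient_data_has_trailing_zero_variance(self, rng):
        basis = rng.normal(size=(2, 57))
        X = rng.normal(size=(100, 2)) @ basis
        m = F.fit_pca(X)
        assert np.all(m.explained_variance_ratio[2:] < 1e-10)

    def test_warns_when_ten_components_explain_little(self, rng):
        # isotropic 57-dim noise: 10 components cannot reach 90%
        with pytest.warns(UserWarning, match="components explain"):
            F.fit_pca(rng.normal(size=(400, 57)))

    def test_zero_variance_columns_pass_through(self, rng):
        X = _structured(rng, 50)
        X[:, 7] = 3.0
        m = F.fit_pca(X)
        Z = F.apply_pca(m, X)
        assert np.all(np.isfinite(Z))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="11 samples"):
            F.fit_pca(rng.normal(size=(10, 57)))
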