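"""Quantization, GLCM, Haralick statistics, rotation-invariant aggregation,
the 400-feature layout, and voxelwise feature maps."""

import numpy as np
import pandas as pd
import pytest
from skimage.feature import graycomatrix, graycoprops

from evradiomics.errors import EmptyCooccurrenceError, ParameterError, ValidationError
from evradiomics.features import (
    AGGREGATIONS,
    DEFAULT_GRAY_LEVELS,
    HARALICK_NAMES,
    HISTOGRAM_NAMES,
    OFFSETS_3D,
    base_texture_stats,
    extract_all,
    feature_map,
    feature_registry,
    glcm,
    histogram_features,
    quantize,
    rotation_invariant_feature_names,
    rotation_invariant_features,
    volume_normalized_features,
)
from evradiomics.io import CTVolume, VOISet
from oracles import brute_glcm, textbook_haralick


def _cube(values):
    arr = np.asarray(values, dtype=float)
    return arr, np.ones(arr.shape, dtype=bool)


class TestQuantize:
    def test_equal_width_halves(self):
        arr, mask = _cube([[[0.0, 1.0, 2.0, 3.0]]])
        q = quantize(arr, mask, G=2)
        np.testing.assert_array_equal(q.levels[mask], [1, 1, 2, 2])

    def test_constant_voi_maps_to_level_one(self):
        arr, mask = _cube(np.full((3, 3, 3), 7.0))
        q = quantize(arr, mask, G=16)
        assert set(q.levels[mask]) == {1}

    def test_uniform_values_fill_levels_evenly(self, rng):
        arr = rng.random((10, 10, 10))
        mask = np.ones(arr.shape, dtype=bool)
        q = quantize(arr, mask, G=8)
        freqs = np.bincount(q.levels[mask], minlength=9)[1:] / 1000.0
        # binomial SE at p=1/8, n=1000 is ~0.010; allow 4 SE
        np.testing.assert_allclose(freqs, 0.125, atol=0.042)

    def test_levels_bounded_and_outside_mask_zero(self, rng):
        arr = rng.normal(size=(6, 6, 6))
        mask = rng.random(arr.shape) > 0.5
        q = quantize(arr, mask, G=5)
        assert q.levels[mask].min() >= 1 and q.levels[mask].max() <= 5
        assert (q.levels[~mask] == 0).all()

    def test_too_few_levels_rejected(self):
        arr, mask = _cube(np.zeros((3, 3, 3)))
        with pytest.raises(ParameterError):
            quantize(arr, mask, G=1)


class TestGLCM:
    def test_single_pair_symmetrized(self):
        arr = np.array([[[1.0, 2.0]]])
        mask = np.ones(arr.shape, dtype=bool)
        q = quantize(arr, mask, G=2)
        m = glcm(q, mask, (0, 0, 1))
        np.testing.assert_allclose(m.matrix, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_region_is_single_diagonal_cell(self):
        arr, mask = _cube(np.full((3, 3, 3), 4.0))
        q = quantize(arr, mask, G=4)
        m = glcm(q, mask, (1, 0, 0))
        expected = np.zeros((4, 4))
        expected[0, 0] = 1.0
        np.testing.assert_allclose(m.matrix, expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_pair_enumeration(self, seed):
        r = np.random.default_rng(seed)
        G = int(r.integers(2, 6))
        shape = tuple(r.integers(2, 6, size=3))
        levels = r.integers(1, G + 1, size=shape).astype(np.int32)
        mask = r.random(shape) > 0.3
        offset = tuple(OFFSETS_3D[r.integers(0, 13)])
        from evradiomics.features import QuantizedVOI
        q = QuantizedVOI(levels=np.where(mask, levels, 0), G=G)
        try:
            m = glcm(q, mask, offset)
        except EmptyCooccurrenceError:
            assert brute_glcm(levels, mask, offset, G).sum() == 0
            return
        np.testing.assert_allclose(m.matrix, brute_glcm(levels, mask, offset, G), atol=1e-12)
        assert m.matrix.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(m.matrix, m.matrix.T, atol=1e-12)

    def test_no_valid_pair_raises(self):
        arr = np.zeros((1, 1, 2))
        mask = np.array([[[True, False]]])
        q = quantize(arr, mask, G=2)
        with pytest.raises(EmptyCooccurrenceError):
            glcm(q, mask, (0, 0, 1))

    def test_zero_offset_rejected(self):
        arr, mask = _cube(np.zeros((2, 2, 2)))
        q = quantize(arr, mask, G=2)
        with pytest.raises(ParameterError):
            glcm(q, mask, (0, 0, 0))


class TestHaralick:
    def test_diagonal_uniform_glcm(self):
        stats = base_texture_stats(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert stats["Contrast"] == pytest.approx(0.0)
        assert stats["Entropy"] == pytest.approx(1.0)  # 1 bit

    def test_antidiagonal_glcm(self):
        stats = base_texture_stats(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert stats["Contrast"] == pytest.approx(1.0)
        assert stats["Energy"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_textbook_direct_summation(self, seed):
        r = np.random.default_rng(seed)
        G = int(r.integers(2, 9))
        M = r.random((G, G))
        M = M + M.T
        P = M / M.sum()
        ours = base_texture_stats(P)
        ref = textbook_haralick(P)
        for name in HARALICK_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_matches_skimage_on_2d_texture(self, rng):
        """Cross-check the GLCM + contrast/energy/correlation path against
        scikit-image on an equivalent 2D problem."""
        G = 6
        img2d = rng.integers(0, G, size=(12, 12)).astype(np.uint8)
        sk = graycomatrix(img2d, [1], [0], levels=G, symmetric=True, normed=True)
        vol = img2d[None, :, :].astype(float)
        mask = np.ones(vol.shape, dtype=bool)
        q = quantize(vol, mask, G)
        assert set(np.unique(q.levels)) == set(np.unique(img2d) + 1)
        m = glcm(q, mask, (0, 0, 1))  # axis-1 step in 2D == angle 0 in skimage
        np.testing.assert_allclose(m.matrix, sk[:, :, 0, 0], atol=1e-12)
        stats = base_texture_stats(m)
        assert stats["Contrast"] == pytest.approx(graycoprops(sk, "contrast")[0, 0])
        assert stats["Energy"] == pytest.approx(graycoprops(sk, "ASM")[0, 0])
        assert stats["Correlation"] == pytest.approx(
            graycoprops(sk, "correlation")[0, 0], abs=1e-10)

    def test_degenerate_correlation_defined_zero(self):
        P = np.zeros((3, 3))
        P[0, 0] = 1.0
        assert base_texture_stats(P)["Correlation"] == 0.0


class TestRotationInvariance:
    def test_exactly_39_features(self, textured_volume):
        volume, voi = textured_volume
        feats = rotation_invariant_features(volume, voi.lesion_masks["TL_1"], G=8)
        assert len(feats) == 39
        assert list(feats) == rotation_invariant_feature_names()

    @pytest.mark.parametrize("transform", [
        lambda a: np.rot90(a, axes=(0, 1)),
        lambda a: np.rot90(a, axes=(0, 2)),
        lambda a: np.rot90(a, axes=(1, 2)),
        lambda a: a[::-1, :, :],
    ])
    def test_invariant_under_grid_rotations_and_reflection(self, textured_volume, transform):
        volume, voi = textured_volume
        mask = voi.lesion_masks["TL_1"]
        base = rotation_invariant_features(volume.data, mask, G=8)
        rot = rotation_invariant_features(transform(volume.data), transform(mask), G=8)
        for name in base:
            assert rot[name] == pytest.approx(base[name], abs=1e-9), name

    def test_constant_voi_has_zero_range_features(self):
        arr = np.full((6, 6, 6), 3.0)
        mask = np.ones(arr.shape, dtype=bool)
        feats = rotation_invariant_features(arr, mask, G=8)
        for stat in HARALICK_NAMES:
            assert feats[f"Range of {stat}"] == pytest.approx(0.0)
            assert feats[f"Variance of {stat}"] == pytest.approx(0.0)

    def test_thin_voi_warns_and_excludes_empty_directions(self):
        arr = np.arange(8, dtype=float).reshape(1, 1, 8)
        mask = np.ones(arr.shape, dtype=bool)
        with pytest.warns(UserWarning, match="no valid voxel pair"):
            feats = rotation_invariant_features(arr, mask, G=4)
        assert len(feats) == 39

    def test_single_voxel_voi_raises(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(EmptyCooccurrenceError), pytest.warns(UserWarning):
            rotation_invariant_features(np.zeros((3, 3, 3)), mask, G=4)


class TestHistogramFeatures:
    def test_exactly_10_named_features(self, rng):
        arr = rng.normal(size=(5, 5, 5))
        feats = histogram_features(arr, np.ones(arr.shape, bool))
        assert list(feats) == list(HISTOGRAM_NAMES)

    def test_constant_voi(self):
        arr = np.full((4, 4, 4), 12.5)
        f = histogram_features(arr, np.ones(arr.shape, bool))
        for key in ("Mean", "Median", "Minimum", "Maximum"):
            assert f[key] == pytest.approx(12.5)
        for key in ("Standard Deviation", "Variance", "Skewness", "Kurtosis"):
            assert f[key] == 0.0

    def test_standard_normal_moments(self):
        r = np.random.default_rng(99)
        arr = r.standard_normal((25, 20, 20))  # 10,000 voxels
        f = histogram_features(arr, np.ones(arr.shape, bool))
        assert f["Mean"] == pytest.approx(0.0, abs=0.05)
        assert f["Standard Deviation"] == pytest.approx(1.0, abs=0.05)
        assert f["Skewness"] == pytest.approx(0.0, abs=0.1)
        assert f["Kurtosis"] == pytest.approx(0.0, abs=0.2)  # excess
        assert f["10th Percentile"] == pytest.approx(-1.2816, abs=0.06)


class TestVolumeNormalization:
    def test_identity_at_unit_volume_and_homogeneity(self):
        feats = {f"f{i}": float(i) for i in range(195)}
        out1 = volume_normalized_features(feats, 1.0)
        assert len(out1) == 195
        assert all(out1[f"f{i} per Volume"] == pytest.approx(i) for i in range(195))
        out2 = volume_normalized_features(feats, 2.0)
        assert all(out2[f"f{i} per Volume"] == pytest.approx(i / 2.0) for i in range(195))

    def test_zero_volume_rejected(self):
        with pytest.raises(ValidationError):
            volume_normalized_features({"a": 1.0}, 0.0)


class TestExtractAll:
    def test_exactly_400_features_partitioned(self, textured_volume):
        volume, voi = textured_volume
        vec = extract_all(volume, voi)["TL_1"]
        assert len(vec) == 400
        reg = feature_registry()
        assert len(reg) == 400 and reg["code"].is_unique and reg["name"].is_unique
        assert (reg["family"].value_counts()
                == pd.Series({"glcm": 195, "glcm_per_volume": 195, "histogram": 10})).all()
        # volume-normalized block is the GLCM block / lesion volume
        from evradiomics.io import voi_volume_cc
        vol_cc = voi_volume_cc(voi.lesion_masks["TL_1"], volume.spacing_mm)
        np.testing.assert_allclose(vec.iloc[205:400].to_numpy(),
                                   vec.iloc[10:205].to_numpy() / vol_cc, rtol=1e-12)

    def test_deterministic(self, textured_volume):
        volume, voi = textured_volume
        v1 = extract_all(volume, voi)["TL_1"]
        v2 = extract_all(volume, voi)["TL_1"]
        pd.testing.assert_series_equal(v1, v2)

    def test_translation_invariance(self, rng):
        lesion_tex = rng.normal(size=(5, 5, 5))
        data = np.full((20, 20, 20), -50.0)
        muscle = np.zeros(data.shape, dtype=bool)
        muscle[1:4, 1:4, 1:4] = True
        data[muscle] = 50.0 + rng.normal(size=int(muscle.sum()))

        def put(at):
            d = data.copy()
            mask = np.zeros(d.shape, dtype=bool)
            sl = tuple(slice(a, a + 5) for a in at)
            mask[sl] = True
            d[sl] = 30.0 + lesion_tex
            return CTVolume(d, (1, 1, 1)), VOISet({"TL_1": mask}, muscle)

        v1 = extract_all(*put((8, 8, 8)))["TL_1"]
        v2 = extract_all(*put((12, 10, 9)))["TL_1"]
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), atol=1e-9)

    def test_glcm_features_invariant_to_affine_rescale_with_muscle_norm(self, textured_volume):
        volume, voi = textured_volume
        rescaled = CTVolume(3.0 * volume.data + 100.0, volume.spacing_mm)
        v1 = extract_all(volume, voi)["TL_1"]
        v2 = extract_all(rescaled, voi)["TL_1"]
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), rtol=1e-9, atol=1e-9)


class TestFeatureMap:
    def test_homogeneous_lesion_gives_zero_range_map(self):
        data = np.full((10, 10, 10), 30.0)
        mask = np.zeros(data.shape, dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        vol = CTVolume(data, (1, 1, 1))
        fmap = feature_map(vol, mask, "Range of Difference Variance", window_radius=1)
        vals = fmap.data[mask]
        assert np.nanmax(np.abs(vals)) == pytest.approx(0.0)
        assert np.isnan(fmap.data[~mask]).all()

    def test_voxel_window_matches_direct_feature_call(self, textured_volume):
        volume, voi = textured_volume
        mask = voi.lesion_masks["TL_1"]
        z, y, x = np.argwhere(mask)[len(np.argwhere(mask)) // 2]
        r = 2
        fmap = feature_map(volume, mask, "Mean of Contrast", window_radius=r, G=8)
        sl = (slice(z - r, z + r + 1), slice(y - r, y + r + 1), slice(x - r, x + r + 1))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = rotation_invariant_features(volume.data[sl], mask[sl], G=8)
        assert fmap.data[z, y, x] == pytest.approx(direct["Mean of Contrast"], rel=1e-12)

    def test_two_texture_composite_separates_regions(self, rng):
        data = np.full((8, 8, 16), 0.0)
        mask = np.zeros(data.shape, dtype=bool)
        mask[1:7, 1:7, 1:15] = True
        # left half: fine checkerboard-like noise; right half: smooth ramp
        data[:, :, :8] = rng.normal(scale=10.0, size=(8, 8, 8))
        data[:, :, 8:] = np.linspace(0, 1, 8)[None, None, :]
        vol = CTVolume(data, (1, 1, 1))
        fmap = feature_map(vol, mask, "Mean of Contrast", window_radius=2, G=4)
        left = np.nanmean(fmap.data[:, :, 2:6][mask[:, :, 2:6]])
        right = np.nanmean(fmap.data[:, :, 10:14][mask[:, :, 10:14]])
        assert left > right

    def test_unknown_feature_name_rejected(self, textured_volume):
        volume, voi = textured_volume
        with pytest.raises(ParameterError):
            feature_map(volume, voi.lesion_masks["TL_1"], "Glittering of Sparkle")
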