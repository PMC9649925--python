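"""Radiomic extractor: manifest contract, sub-bands, first-order, texture."""

import numpy as np
import pytest

from strokerad import radiomics
from strokerad.errors import DataError, ExclusionError, ShapeError


class TestManifest:
    def test_feature_count_identity(self):
        m = radiomics.feature_manifest()
        assert len(m) == 513
        assert m["name"].is_unique
        per_domain = m.groupby("domain").size()
        assert (per_domain == 57).all() and len(per_domain) == 9
        fam = m.groupby(["domain", "family"]).size().unstack()
        assert (fam["intensity"] == 18).all()
        assert (fam["texture"] == 39).all()


class TestWaveletSubbands:
    def test_eight_shape_preserving_subbands(self, lesion_subject):
        _, adc, _ = lesion_subject
        bands = radiomics.wavelet_subbands(adc)
        assert set(bands) == set(radiomics.SUBBAND_NAMES)
        assert all(b.shape == adc.shape for b in bands.values())

    def test_constant_volume_has_zero_detail(self):
        bands = radiomics.wavelet_subbands(np.full((5, 7, 9), 3.25))
        for name in radiomics.SUBBAND_NAMES:
            if name != "LLL":
                assert np.allclose(bands[name], 0.0)

    def test_rejects_thin_volume(self):
        with pytest.raises(ShapeError):
            radiomics.wavelet_subbands(np.zeros((1, 8, 8)))


class TestIntensityFeatures:
    def test_hand_computed_example(self):
        f = radiomics.intensity_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert len(f) == 18 and set(f) == set(radiomics.FIRST_ORDER_NAMES)
        assert f["fo_mean"] == 2.5
        assert f["fo_range"] == 3.0
        assert f["fo_energy"] == 30.0  # 1 + 4 + 9 + 16

    def test_constant_region_conventions(self):
        f = radiomics.intensity_features(np.full(40, 7.0))
        assert f["fo_mean"] == 7.0
        assert f["fo_variance"] == 0.0
        assert f["fo_entropy"] == 0.0
        assert f["fo_skewness"] == 0.0 and f["fo_kurtosis"] == 0.0
        assert f["fo_uniformity"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            radiomics.intensity_features(np.array([]))


class TestTextureFeatures:
    def test_exactly_39_features(self, lesion_subject):
        _, adc, mask = lesion_subject
        f = radiomics.texture_features(adc, mask.astype(bool))
        assert len(f) == 39 and set(f) == set(radiomics.TEXTURE_NAMES)

    def test_constant_lesion_conventions(self):
        vol = np.full((6, 8, 8), 2.0)
        mask = np.zeros((6, 8, 8), dtype=bool)
        mask[2:5, 2:6, 2:6] = True
        f = radiomics.texture_features(vol, mask)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_joint_entropy"] == 0.0
        assert f["glcm_id"] == 1.0 and f["glcm_idm"] == 1.0
        assert f["glcm_maximum_probability"] == 1.0

    def test_checkerboard_contrast_is_one(self):
        # 1-voxel-thick 2-level checkerboard; horizontal distance-1 offset only:
        # every co-occurring pair differs by exactly one level
        yy, xx = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        slab = ((yy + xx) % 2).astype(float)[None]
        mask = np.ones_like(slab, dtype=bool)
        q = radiomics.quantize(slab, mask, 2)
        p = radiomics.glcm_matrix(q, 2, directions=[(0, 0, 1)])
        f = radiomics.glcm_features(p)
        assert f["glcm_contrast"] == pytest.approx(1.0)

    def test_single_voxel_mask_degenerates_to_constant(self):
        vol = np.random.default_rng(0).random((5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        f = radiomics.texture_features(vol, mask)
        assert f["glcm_contrast"] == 0.0
        assert np.isfinite(list(f.values())).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            radiomics.texture_features(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool))

    def test_glcm_matches_skimage_on_2d_slab(self):
        """Single-direction GLCM counts agree with scikit-image's 2D matrix."""
        skimage = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(3)
        img = rng.integers(0, 4, size=(12, 12))
        q3d = (img + 1)[None].astype(np.int32)  # levels 1..4, full mask
        ours = radiomics.glcm_matrix(q3d, 4, directions=[(0, 0, 1)])
        ref = skimage.graycomatrix(img.astype(np.uint8), distances=[1], angles=[0],
                                   levels=4, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestExtractFeatures:
    def test_vector_length_and_determinism(self, lesion_subject):
        _, adc, mask = lesion_subject
        fv1 = radiomics.extract_features(adc, mask.astype(bool))
        fv2 = radiomics.extract_features(adc, mask.astype(bool))
        assert len(fv1) == 513
        np.testing.assert_array_equal(fv1.values, fv2.values)
        assert np.isfinite(fv1.values).all()

    def test_small_lesion_excluded(self, lesion_subject):
        _, adc, _ = lesion_subject
        mask = np.zeros(adc.shape, dtype=bool)
        mask[10, 10:17, 10:17] = True  # 49 voxels
        assert mask.sum() == 49
        with pytest.raises(ExclusionError):
            radiomics.extract_features(adc, mask)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        vol = np.zeros((16, 20, 20))
        mask = np.zeros((16, 20, 20), dtype=bool)
        mask[4:9, 4:10, 4:10] = True
        vol[mask] = rng.random(int(mask.sum())) + 1.0
        fv = radiomics.extract_features(vol, mask, enforce_min_size=False)
        vol2 = np.roll(vol, (2, 3, 1), axis=(0, 1, 2))
        mask2 = np.roll(mask, (2, 3, 1), axis=(0, 1, 2))
        fv2 = radiomics.extract_features(vol2, mask2, enforce_min_size=False)
        np.testing.assert_allclose(fv.values, fv2.values, rtol=1e-9, atol=1e-9)

    def test_intensity_shift_behavior(self, lesion_subject):
        """Adding a constant shifts location features and leaves image-domain
        dispersion and texture (min-max quantized) unchanged."""
        _, adc, mask = lesion_subject
        m = mask.astype(bool)
        base = radiomics.extract_features(adc, m)
        shifted = radiomics.extract_features(adc + 5.0, m)
        for name in ("image_fo_mean", "image_fo_median", "image_fo_p10", "image_fo_p90"):
            assert shifted[name] == pytest.approx(base[name] + 5.0, rel=1e-9)
        for name in ("image_fo_variance", "image_fo_std", "image_fo_iqr"):
            assert shifted[name] == pytest.approx(base[name], rel=1e-9)
        for name in base.names:
            if "glcm" in name and name.startswith("image"):
                assert shifted[name] == pytest.approx(base[name], rel=1e-9, abs=1e-12)

    def test_texture_correlation_length_moves_glcm_correlation(self):
        """Smoother lesion interiors (longer correlation length) raise the
        co-occurrence correlation feature on paired phantoms."""
        from strokerad import phantom
        vals = []
        for scale in (0.3, 2.5):
            per_seed = []
            for seed in range(4):
                rng = np.random.default_rng(100 + seed)
                _, adc, mask = phantom.synthesize_lesion_pair(
                    (24, 40, 40), 300, scale, rng, texture_amplitude=0.15, noise_sd=0.0)
                fv = radiomics.extract_features(adc, mask.astype(bool))
                per_seed.append(fv["image_glcm_correlation"])
            vals.append(np.mean(per_seed))
        assert vals[1] > vals[0]
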