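"""Intensity, shape, sharpness, filter-bank features and the registry."""

import numpy as np
import pytest

from kernelharm.radfeat import (
    FAMILIES,
    REGISTRY,
    extract_all,
    feature_groups,
    feature_names,
)
from kernelharm.radfeat.intensity import edge_freq_mean, intensity_features
from kernelharm.radfeat.shape import shape_features, sigmoid_slope_features
from kernelharm.radfeat.filters import (
    laws_features,
    log_features,
    log_kernel,
    wavelet_features,
)


def ball_mask(shape=(16, 16, 16), radius=5.0):
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2.0
    return np.sqrt(sum((idx[k] - c[k]) ** 2 for k in range(3))) <= radius


class TestIntensity:
    def test_symmetric_values_zero_skewness(self):
        vol = np.repeat([-1.0, 0.0, 1.0], 9).reshape(3, 3, 3)
        mask = np.ones((3, 3, 3), dtype=bool)
        values, _ = intensity_features(vol, mask)
        assert values["Intensity_Skewness_3D"] == pytest.approx(0.0, abs=1e-12)

    def test_skewness_direct_moment_oracle(self):
        vals = np.array([0.0, 0.0, 0.0, 1.0])
        vol = vals.reshape(4, 1, 1)
        mask = np.ones_like(vol, dtype=bool)
        values, _ = intensity_features(vol, mask)
        m = vals - vals.mean()
        expected = np.mean(m**3) / np.mean(m**2) ** 1.5
        assert values["Intensity_Skewness_3D"] == pytest.approx(expected)

    def test_single_slice_2d_equals_3d(self, rng):
        vol = rng.normal(size=(5, 5, 1))
        mask = np.ones((5, 5, 1), dtype=bool)
        values, _ = intensity_features(vol, mask)
        assert values["Intensity_Skewness_2D"] == pytest.approx(
            values["Intensity_Skewness_3D"]
        )

    def test_zero_variance_flagged_zero(self):
        vol = np.full((3, 3, 3), 5.0)
        mask = np.ones((3, 3, 3), dtype=bool)
        values, undefined = intensity_features(vol, mask)
        assert values["Intensity_Skewness_3D"] == 0.0
        assert "Intensity_Skewness_3D" in undefined


class TestEdgeFreq:
    def test_constant_volume_zero(self):
        vol = np.full((6, 6, 6), 3.0)
        assert edge_freq_mean(vol, np.ones_like(vol, dtype=bool)) == 0.0

    def test_linear_ramp_interior_slope(self):
        g = 2.5
        vol = np.tile(np.arange(8.0) * g, (8, 8, 1)).transpose(2, 0, 1)
        mask = np.zeros_like(vol, dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True  # interior: central differences exact
        assert edge_freq_mean(vol, mask) == pytest.approx(g)

    def test_matches_direct_finite_difference_oracle(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        gz, gy, gx = np.gradient(vol)
        expected = np.sqrt(gz**2 + gy**2 + gx**2)[mask].mean()
        assert edge_freq_mean(vol, mask) == pytest.approx(expected)


class TestShape:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        values, _ = shape_features(mask)
        assert values["Shape_Volume_mm3"] == 1.0
        assert values["Shape_SurfaceArea_mm2"] == 6.0

    def test_cube_closed_forms(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        values, _ = shape_features(mask)
        assert values["Shape_Volume_mm3"] == 27.0
        assert values["Shape_SurfaceArea_mm2"] == 54.0
        assert values["Shape_MaxDiameter3D_mm"] == pytest.approx(2 * np.sqrt(3))
        assert values["Shape_Compactness"] == pytest.approx(
            36 * np.pi * 27**2 / 54**3
        )

    def test_anisotropic_spacing(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        values, _ = shape_features(mask, spacing=(2.0, 1.0, 1.0))
        assert values["Shape_Volume_mm3"] == 2.0
        # two 1x1 faces (normal to z) + four 2x1 faces
        assert values["Shape_SurfaceArea_mm2"] == 2 * 1.0 + 4 * 2.0


class TestSigmoidSlope:
    def _lesion(self, blur):
        from scipy import ndimage

        mask = ball_mask((24, 24, 24), 6.0)
        vol = np.where(mask, 0.0, -800.0)
        if blur > 0:
            vol = ndimage.gaussian_filter(vol, blur)
        return vol, mask

    def test_slope_decreases_with_blur(self):
        slopes = []
        for blur in (0.5, 1.5, 3.0):
            vol, mask = self._lesion(blur)
            values, undefined = sigmoid_slope_features(vol, mask)
            assert not undefined
            slopes.append(values["Sigmoid_Slope"])
        assert slopes[0] > slopes[1] > slopes[2]

    def test_constant_volume_undefined(self):
        mask = ball_mask((16, 16, 16), 4.0)
        vol = np.zeros((16, 16, 16))
        _, undefined = sigmoid_slope_features(vol, mask)
        assert "Sigmoid_Slope" in undefined

    def test_exact_logistic_parameter_recovery(self):
        # build a volume whose radial profile is exactly the fitted model
        b, s, t0 = -700.0, 1.2, 6.0
        shape = (32, 32, 32)
        idx = np.indices(shape, dtype=float)
        c = (np.asarray(shape) - 1) / 2.0
        r = np.sqrt(sum((idx[k] - c[k]) ** 2 for k in range(3)))
        vol = 0.0 + b / (1.0 + np.exp(-(r - t0) / s))
        mask = r <= t0
        values, undefined = sigmoid_slope_features(vol, mask)
        assert not undefined
        assert values["Sigmoid_Slope"] == pytest.approx(abs(b) / (4 * s), rel=1e-3)


class TestLoG:
    def test_kernel_sum_near_zero(self):
        for sigma in (1.5, 2.5):
            assert abs(log_kernel(sigma).sum()) < 1e-6

    def test_constant_volume_entropy_zero(self):
        vol = np.full((16, 16, 16), 100.0)
        mask = ball_mask((16, 16, 16), 4.0)
        values, _ = log_features(vol, mask, sigmas=(1.5,))
        assert values["LoG_Entropy_p1"] == 0.0
        assert abs(values["LoG_Mean_p1"]) < 1e-8

    def test_impulse_response_center_value(self):
        kern = log_kernel(1.5)
        n = kern.shape[0]
        vol = np.zeros((n + 4, n + 4, n + 4))
        center = tuple(s // 2 for s in vol.shape)
        vol[center] = 1.0
        from scipy import signal

        resp = signal.fftconvolve(vol, kern, mode="same")
        assert resp[center] == pytest.approx(kern[n // 2, n // 2, n // 2], abs=1e-10)

    def test_oversized_kernel_rejected(self):
        vol = np.zeros((8, 8, 8))
        mask = np.ones((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            log_features(vol, mask, sigmas=(2.5,))  # 21^3 kernel > 8^3 volume


class TestLawsWavelet:
    def test_constant_roi_detail_energies_zero(self):
        vol = np.full((16, 16, 16), 5.0)
        mask = ball_mask((16, 16, 16), 5.0)
        laws, _ = laws_features(vol, mask)
        for name, v in laws.items():
            if "E5" in name or "S5" in name:
                assert v == pytest.approx(0.0, abs=1e-9), name
        wav, undefined = wavelet_features(vol, mask)
        assert not undefined
        for band in ("AAD", "ADA", "ADD", "DAA", "DAD", "DDA", "DDD"):
            assert wav[f"Wavelet_{band}"] == pytest.approx(0.0, abs=1e-9)

    def test_lowpass_kernel_sum_on_constant(self):
        c = 3.0
        vol = np.full((12, 12, 12), c)
        mask = ball_mask((12, 12, 12), 3.0)
        laws, _ = laws_features(vol, mask)
        # L5 coefficients sum to 16; the separable 3D kernel sums to 16^3
        assert laws["Laws_L5L5L5"] == pytest.approx(c * 16**3)

    def test_homogeneity_degree_one(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        mask = ball_mask((16, 16, 16), 5.0)
        laws1, _ = laws_features(vol, mask)
        laws2, _ = laws_features(2 * vol, mask)
        for k in laws1:
            assert laws2[k] == pytest.approx(2 * laws1[k], rel=1e-10)

    def test_small_bbox_wavelet_flagged(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        _, undefined = wavelet_features(np.zeros((6, 6, 6)), mask)
        assert len(undefined) == 8


class TestRegistryAndExtractAll:
    def test_registry_spans_89_features_11_families_23_groups(self):
        assert len(feature_names()) == 89
        assert len(FAMILIES) == 11
        assert len(set(feature_groups().values())) == 23
        # every feature in exactly one family and group
        assert len({d.name for d in REGISTRY}) == len(REGISTRY)

    def test_extract_all_deterministic_and_complete(self, tiny_cohort):
        rec = tiny_cohort.records[0]
        a = extract_all(rec.smooth_image, rec.mask.values)
        b = extract_all(rec.smooth_image, rec.mask.values)
        assert a.values == b.values
        assert a.undefined == b.undefined
        assert list(a.values) == feature_names()

    def test_shape_family_identical_across_renderings(self, tiny_cohort):
        rec = tiny_cohort.records[0]
        a = extract_all(rec.smooth_image, rec.mask.values)
        b = extract_all(rec.sharp_image, rec.mask.values)
        shape_feats = [d.name for d in REGISTRY if d.family == "shape"]
        for f in shape_feats:
            assert a.values[f] == b.values[f]

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            extract_all(np.zeros((4, 4, 4)), np.ones((5, 5, 5), dtype=bool))
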