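"""Color statistics, histogram entropy and GLCM texture features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spicevision as sv
from spicevision.features import FEATURE_NAMES, N_FEATURES, DEFAULT_OFFSETS


def naive_glcm(plane, levels, offsets, symmetric=True):
    """Brute-force pair enumeration oracle for co-occurrence counting."""
    from spicevision.features import quantize_plane

    q = quantize_plane(np.asarray(plane, dtype=float), levels)
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    counts[q[r, c], q[rr, cc]] += 1
    if symmetric:
        counts = counts + counts.T
    if counts.sum() == 0:
        counts[0, 0] = 1
    return counts / counts.sum()


class TestChannelStats:
    def test_constant_plane_conventions(self):
        s = sv.channel_stats(np.full((4, 4), 0.4))
        assert s["mean"] == s["median"] == s["mode"] == s["min"] == s["max"] == 0.4
        assert s["std"] == s["cv"] == s["skewness"] == s["kurtosis"] == 0.0

    def test_two_point_plane_moments(self):
        s = sv.channel_stats(np.array([0.0, 0.0, 1.0, 1.0]))
        assert s["mean"] == 0.5
        assert s["std"] == pytest.approx(np.sqrt(1 / 3), abs=1e-10)
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert s["kurtosis"] == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_plane_kurtosis_near_three(self):
        x = np.random.default_rng(5).normal(0.5, 0.1, size=(256, 256))
        assert sv.channel_stats(x)["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_empty_plane_rejected(self):
        with pytest.raises(ValueError):
            sv.channel_stats(np.empty((0,)))


class TestHistogramEntropy:
    def test_constant_plane_zero(self):
        assert sv.histogram_entropy(np.full((8, 8), 0.3)) == 0.0

    def test_uniform_256_bins_is_8_bits(self):
        x = np.repeat(np.arange(256) / 255.0, 4)
        assert sv.histogram_entropy(x) == pytest.approx(8.0, abs=1e-12)

    def test_two_equal_bins_one_bit(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert sv.histogram_entropy(x, bins=2) == pytest.approx(1.0)


class TestGLCM:
    def test_horizontal_stripes_single_offset(self):
        g = sv.glcm_compute(np.array([[0.0, 0.0], [1.0, 1.0]]),
                            levels=2, offsets=((0, 1),))
        assert g.matrix[0, 0] == 0.5 and g.matrix[1, 1] == 0.5
        assert g.matrix[0, 1] == 0.0

    def test_checkerboard_single_offset(self):
        g = sv.glcm_compute(np.array([[0.0, 1.0], [1.0, 0.0]]),
                            levels=2, offsets=((0, 1),))
        assert g.matrix[0, 1] == 0.5 and g.matrix[1, 0] == 0.5

    def test_constant_plane_all_mass_at_origin(self):
        g = sv.glcm_compute(np.full((3, 3), 0.7), levels=4)
        assert g.matrix[0, 0] == 1.0 and g.matrix.sum() == 1.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 4),
           st.integers(2, 5), st.integers(2, 5))
    def test_matches_naive_enumeration(self, seed, levels, h, w):
        plane = np.random.default_rng(seed).random((h, w))
        g = sv.glcm_compute(plane, levels=levels)
        expected = naive_glcm(plane, levels, DEFAULT_OFFSETS)
        assert np.allclose(g.matrix, expected, atol=1e-12)
        assert g.matrix.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.matrix, g.matrix.T)


class TestGLCMFeatures:
    def test_diagonal_two_level(self):
        g = sv.GLCM(matrix=np.array([[0.5, 0.0], [0.0, 0.5]]), levels=2)
        f = sv.glcm_features(g)
        assert f == {"energy": 0.5, "contrast": 0.0,
                     "correlation": 1.0, "homogeneity": 1.0}

    def test_antidiagonal_two_level(self):
        g = sv.GLCM(matrix=np.array([[0.0, 0.5], [0.5, 0.0]]), levels=2)
        f = sv.glcm_features(g)
        assert f["energy"] == 0.5
        assert f["contrast"] == 1.0
        assert f["homogeneity"] == 0.5
        assert f["correlation"] == pytest.approx(-1.0)

    def test_point_mass(self):
        m = np.zeros((2, 2))
        m[0, 0] = 1.0
        f = sv.glcm_features(sv.GLCM(matrix=m, levels=2))
        assert f == {"energy": 1.0, "contrast": 0.0,
                     "correlation": 1.0, "homogeneity": 1.0}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_feature_bounds_on_random_planes(self, seed):
        plane = np.random.default_rng(seed).random((6, 6))
        f = sv.glcm_features(sv.glcm_compute(plane, levels=4))
        assert 0 < f["energy"] <= 1
        assert 0 < f["homogeneity"] <= 1
        assert -1 - 1e-12 <= f["correlation"] <= 1 + 1e-12
        assert f["contrast"] >= 0

    def test_transpose_invariance_of_symmetric_features(self, rng):
        plane = rng.random((8, 8))
        f1 = sv.glcm_features(sv.glcm_compute(plane))
        # transposing the image mirrors the offset set onto itself
        f2 = sv.glcm_features(sv.glcm_compute(plane.T))
        for key in ("contrast", "correlation", "homogeneity"):
            assert f1[key] == pytest.approx(f2[key], abs=1e-12)


class TestExtractFeatures:
    def test_vector_has_266_stable_names(self, rng):
        stack = sv.to_channels(rng.random((16, 16, 3)))
        fv = sv.extract_features(stack)
        assert len(fv) == N_FEATURES == 266
        assert list(fv) == list(FEATURE_NAMES)

    def test_constant_gray_image_conventions(self):
        stack = sv.to_channels(np.full((16, 16, 3), 0.4))
        fv = sv.extract_features(stack)
        # luma weights sum to 0.9999, hence the 1e-4-scale slack
        assert fv["mean_gray"] == pytest.approx(0.4, abs=1e-4)
        assert all(v == 0.0 for k, v in fv.items() if k.startswith("contrast_"))
        assert all(v == 1.0 for k, v in fv.items() if k.startswith("energy_"))

    def test_channels_independent_of_blue_offset(self, rng):
        img = rng.random((16, 16, 3)) * 0.5
        img2 = img.copy()
        img2[..., 2] += 0.2
        f1 = sv.extract_features(sv.to_channels(img))
        f2 = sv.extract_features(sv.to_channels(img2))
        for name in FEATURE_NAMES:
            if name.endswith(("_R", "_G")):
                assert f1[name] == pytest.approx(f2[name], abs=1e-12)
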