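import numpy as np
import pytest
from skimage.feature import graycomatrix

from histofusion.handcrafted import (
    DWTConfig, FCHConfig, GLCMConfig, HandcraftedConfig, LBPConfig,
    dwt_features, fch_features, glcm_features, glcm_matrix, handcrafted_vector,
    haralick_features, lbp_code, lbp_code_from_neighbors, lbp_code_map,
    lbp_features, quantize_gray, to_grayscale, GLCMMatrix,
)


class TestDWT:
    def test_constant_image(self):
        out = dwt_features(np.full((8, 8), 10.0))
        # LL mean = 2c under the orthonormal convention; every detail stat 0
        assert out[0] == pytest.approx(20.0)
        assert np.allclose(out[1:], 0.0)

    def test_hand_computed_2x2_haar(self):
        out = dwt_features(np.array([[1.0, 2.0], [3.0, 4.0]]))
        # 1x1 subbands: (value, 0, 0) for LL=5, LH=-2, HL=-1, HH=0
        expected = [5, 0, 0, -2, 0, 0, -1, 0, 0, 0, 0, 0]
        assert np.allclose(out, expected)

    def test_energy_conservation(self, rng):
        g = rng.uniform(0, 255, size=(16, 16))
        import pywt
        ll, (lh, hl, hh) = pywt.dwt2(g, "haar")
        total = sum((b ** 2).sum() for b in (ll, lh, hl, hh))
        assert total == pytest.approx((g ** 2).sum(), rel=1e-12)

    def test_odd_dimensions_cropped(self, rng):
        g = rng.uniform(0, 255, size=(17, 15))
        assert np.allclose(dwt_features(g), dwt_features(g[:16, :14]))

    def test_length_is_twelve(self, sample_images):
        assert dwt_features(to_grayscale(sample_images[0])).shape == (12,)


def oracle_lbp_codes(gray, cfg):
    """Independent per-pixel double-loop LBP oracle."""
    g = np.asarray(gray, dtype=np.float64)
    rad = int(np.ceil(cfg.R))
    codes = []
    p_idx = np.arange(cfg.P)
    theta = 2.0 * np.pi * p_idx / cfg.P
    for r in range(rad, g.shape[0] - rad):
        for c in range(rad, g.shape[1] - rad):
            code = 0
            for p in range(cfg.P):
                rr = r - cfg.R * np.sin(theta[p])
                cc = c + cfg.R * np.cos(theta[p])
                if abs(rr - round(rr)) < 1e-8:
                    rr = round(rr)
                if abs(cc - round(cc)) < 1e-8:
                    cc = round(cc)
                r0, c0 = int(np.floor(rr)), int(np.floor(cc))
                fr, fc = rr - r0, cc - c0
                val = ((1 - fr) * (1 - fc) * g[r0, c0]
                       + (1 - fr) * fc * g[r0, min(c0 + 1, g.shape[1] - 1)]
                       + fr * (1 - fc) * g[min(r0 + 1, g.shape[0] - 1), c0]
                       + fr * fc * g[min(r0 + 1, g.shape[0] - 1),
                                     min(c0 + 1, g.shape[1] - 1)])
                if np.round(val, 8) >= g[r, c]:
                    code += 1 << p
            codes.append(code)
    return np.array(codes)


class TestLBP:
    def test_constant_neighborhood_gives_all_ones_code(self):
        cfg = LBPConfig(P=8, R=1.0, n_bins=16)
        g = np.full((5, 5), 7.0)
        assert lbp_code(g, cfg, (2, 2)) == 2 ** 8 - 1

    def test_code_from_sampled_neighbors_matches_bit_sum(self):
        # bits (0,0,0,0,1,1,1,1) -> 2^4 + 2^5 + 2^6 + 2^7 = 240
        assert lbp_code_from_neighbors([1, 2, 3, 4, 6, 7, 8, 9], 5) == 240

    def test_code_bounds(self, rng):
        cfg = LBPConfig(P=8, R=1.0, n_bins=16)
        g = rng.uniform(0, 255, size=(8, 8))
        codes = lbp_code_map(g, cfg)
        assert codes.min() >= 0 and codes.max() <= cfg.code_max

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("cfg", [LBPConfig(P=8, R=1.0, n_bins=16),
                                     LBPConfig(P=15, R=2.0, n_bins=203)])
    def test_codes_match_brute_force_oracle(self, cfg, seed):
        g = np.random.default_rng(seed).uniform(0, 255, size=(12, 12))
        assert np.array_equal(lbp_code_map(g, cfg).ravel(), oracle_lbp_codes(g, cfg))

    def test_histogram_matches_oracle_counts(self, rng):
        cfg = LBPConfig(P=8, R=1.0, n_bins=16)
        g = rng.uniform(0, 255, size=(10, 10))
        hist = lbp_features(g, cfg)
        codes = oracle_lbp_codes(g, cfg)
        expected = np.histogram(codes, bins=16, range=(0, 255))[0] / codes.size
        assert np.allclose(hist, expected)

    def test_constant_image_mass_in_top_bin(self):
        hist = lbp_features(np.full((16, 16), 50.0))
        assert hist[-1] == pytest.approx(1.0)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_default_length_203_and_sums_to_one(self, sample_images):
        hist = lbp_features(to_grayscale(sample_images[2]))
        assert hist.shape == (203,)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_border_pixel_rejected(self):
        with pytest.raises(ValueError):
            lbp_code(np.zeros((8, 8)), LBPConfig(P=8, R=2.0), (1, 1))


class TestFCH:
    centers = np.array([[0, 0, 0], [255, 0, 0], [0, 255, 0], [0, 0, 255],
                        [255, 255, 0], [255, 0, 255], [0, 255, 255], [255, 255, 255],
                        [128, 0, 0], [0, 128, 0], [0, 0, 128], [128, 128, 0],
                        [128, 0, 128], [0, 128, 128], [128, 128, 128], [64, 64, 64]],
                       dtype=float)

    def cfg(self):
        return FCHConfig(bin_centers=self.centers)

    def test_single_color_at_center_is_indicator(self):
        img = np.tile(np.array([255.0, 0.0, 0.0]), (8, 8, 1))
        hist = fch_features(img, self.cfg())
        expected = np.zeros(16)
        expected[1] = 1.0
        assert np.allclose(hist, expected)

    def test_two_color_half_half(self):
        img = np.zeros((8, 8, 3))
        img[:4] = [255, 0, 0]
        img[4:] = [0, 255, 0]
        hist = fch_features(img, self.cfg())
        assert hist[1] == pytest.approx(0.5)
        assert hist[2] == pytest.approx(0.5)

    def test_membership_arithmetic_single_pixel(self):
        """Off-center pixel: u_k proportional to 1/d_k^2 at m=2."""
        img = np.array([[[100.0, 50.0, 25.0]]])
        hist = fch_features(img, self.cfg())
        d2 = ((np.array([100.0, 50.0, 25.0]) - self.centers) ** 2).sum(axis=1)
        expected = (1.0 / d2) / (1.0 / d2).sum()
        assert np.allclose(hist, expected)

    def test_default_centers_deterministic_and_distinct(self):
        from histofusion.handcrafted import default_fch_centers
        c1 = default_fch_centers(FCHConfig(seed=3))
        c2 = default_fch_centers(FCHConfig(seed=3))
        assert np.array_equal(c1, c2)
        assert len(np.unique(np.round(c1, 6), axis=0)) == 16

    def test_sums_to_one_and_length_16(self, sample_images):
        hist = fch_features(sample_images[1])
        assert hist.shape == (16,)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)


class TestGLCM:
    def test_constant_image_single_diagonal_entry(self):
        m = glcm_matrix(np.zeros((4, 4)), d=1, angle=0, levels=8)
        assert m.probabilities[0, 0] == pytest.approx(1.0)

    def test_2x2_pair_enumeration(self):
        m = glcm_matrix(np.array([[0, 1], [0, 1]]), d=1, angle=0, levels=2,
                        prequantized=True)
        assert np.allclose(m.probabilities, [[0.0, 0.5], [0.5, 0.0]])

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("angle,sk_angle", [(0, 0), (45, np.pi / 4),
                                                (90, np.pi / 2), (135, 3 * np.pi / 4)])
    def test_matches_skimage_reference(self, seed, angle, sk_angle):
        """skimage.graycomatrix is the independent co-occurrence oracle."""
        q = np.random.default_rng(seed).integers(0, 8, size=(12, 12))
        ours = glcm_matrix(q, d=1, angle=angle, levels=8, prequantized=True)
        ref = graycomatrix(q.astype(np.uint8), [1], [sk_angle], levels=8,
                           symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(ours.probabilities, ref)

    def test_probabilities_sum_to_one(self, rng):
        g = rng.uniform(0, 255, size=(16, 16))
        for angle in (0, 45, 90, 135):
            assert glcm_matrix(g, angle=angle).probabilities.sum() == pytest.approx(1.0)

    def test_quantization_levels(self):
        q = quantize_gray(np.array([0.0, 31.9, 32.0, 255.0]), 8)
        assert q.tolist() == [0, 0, 1, 7]

    def test_image_too_small_for_offset(self):
        with pytest.raises(ValueError):
            glcm_matrix(np.zeros((2, 2)), d=5, angle=0, levels=2)


class TestHaralick:
    def test_degenerate_single_entry(self):
        p = np.zeros((8, 8))
        p[0, 0] = 1.0
        feats = haralick_features([GLCMMatrix(p, 8, 1, 0)])
        asm, contrast, entropy = feats[0], feats[1], feats[8]
        assert asm == pytest.approx(1.0)
        assert contrast == pytest.approx(0.0)
        assert entropy == pytest.approx(0.0)

    def test_uniform_two_level_closed_form(self):
        p = np.full((2, 2), 0.25)
        feats = haralick_features([GLCMMatrix(p, 2, 1, 0)])
        assert feats[0] == pytest.approx(0.25)   # ASM
        assert feats[1] == pytest.approx(0.5)    # contrast
        assert feats[8] == pytest.approx(2.0)    # entropy, bits
        assert feats[2] == pytest.approx(0.0)    # correlation of independent levels

    def test_closed_form_full_vector(self):
        """All 13 statistics of p = [[.25,.25],[.25,.25]] by hand."""
        p = np.full((2, 2), 0.25)
        feats = haralick_features([GLCMMatrix(p, 2, 1, 0)])
        # marginals uniform: mu = .5, var = .25; p_sum = (.25,.5,.25); p_diff = (.5,.5)
        expected = [0.25, 0.5, 0.0, 0.25, 0.75, 1.0, 0.5, 1.5, 2.0,
                    0.25, 1.0, (2.0 - 2.0) / 1.0, np.sqrt(1 - np.exp(-2 * (2.0 - 2.0)))]
        assert np.allclose(feats, expected)

    def test_angle_averaging(self, rng):
        g = rng.uniform(0, 255, size=(16, 16))
        per_angle = [haralick_features([glcm_matrix(g, angle=a)]) for a in
                     (0, 45, 90, 135)]
        avg = glcm_features(g)
        assert np.allclose(avg, np.mean(per_angle, axis=0))
        assert avg.shape == (13,)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            haralick_features([GLCMMatrix(np.ones((2, 2)), 2, 1, 0)])


class TestHandcraftedVector:
    def test_length_244_and_slice_back(self, sample_images):
        cfg = HandcraftedConfig()
        cfg.fch = FCHConfig(bin_centers=TestFCH.centers)
        img = sample_images[0]
        v = handcrafted_vector(img, cfg)
        assert v.shape == (244,)
        gray = to_grayscale(img)
        assert np.allclose(v[:12], dwt_features(gray, cfg.dwt))
        assert np.allclose(v[12:215], lbp_features(gray, cfg.lbp))
        assert np.allclose(v[215:231], fch_features(img, cfg.fch))
        assert np.allclose(v[231:], glcm_features(gray, cfg.glcm))

    def test_pure_function(self, sample_images):
        img = sample_images[3]
        assert np.array_equal(handcrafted_vector(img), handcrafted_vector(img))

    def test_finite_on_all_classes(self, sample_images):
        for img in sample_images:
            assert np.all(np.isfinite(handcrafted_vector(img)))
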