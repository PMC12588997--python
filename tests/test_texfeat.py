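"""Feature bank oracles: GLCM pair counting, Parseval identities, counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafchem.msio import BAND_ORDER
from leafchem.texfeat import (
    TextureConfig,
    extract_all,
    feature_names,
    fourier_features,
    gabor_features,
    glcm_features,
    lbp_features,
    spectral_means,
    texture_feature_names,
    wavelet_features,
)


# ---------------------------------------------------------------------------
# brute-force GLCM oracle: explicit pair counting + textbook statistics
# ---------------------------------------------------------------------------

def oracle_glcm(image: np.ndarray, levels: int, distance: int,
                angles_deg: tuple) -> np.ndarray:
    lo, hi = image.min(), image.max()
    q = np.minimum(np.floor((image - lo) / (hi - lo) * levels), levels - 1).astype(int)
    h, w = q.shape
    stats_per_angle = []
    for deg in angles_deg:
        # skimage angle convention: offset (row, col) = (-d*sin, d*cos)
        dr = -int(round(distance * np.sin(np.deg2rad(deg))))
        dc = int(round(distance * np.cos(np.deg2rad(deg))))
        P = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    P[q[r, c], q[r2, c2]] += 1
                    P[q[r2, c2], q[r, c]] += 1  # symmetric
        P /= P.sum()
        i = np.arange(levels)[:, None]
        j = np.arange(levels)[None, :]
        contrast = np.sum(P * (i - j) ** 2)
        dissim = np.sum(P * np.abs(i - j))
        homog = np.sum(P / (1.0 + (i - j) ** 2))
        energy = np.sqrt(np.sum(P ** 2))
        mu_i = np.sum(P * i)
        mu_j = np.sum(P * j)
        si = np.sqrt(np.sum(P * (i - mu_i) ** 2))
        sj = np.sqrt(np.sum(P * (j - mu_j) ** 2))
        corr = 1.0 if si * sj == 0 else np.sum(P * (i - mu_i) * (j - mu_j)) / (si * sj)
        stats_per_angle.append([contrast, dissim, homog, energy, corr])
    return np.mean(stats_per_angle, axis=0)


class TestGLCM:
    def test_constant_image_degenerate_values(self):
        out = glcm_features(np.full((8, 8), 3.7))
        np.testing.assert_allclose(out, [0.0, 0.0, 1.0, 1.0, 1.0])

    def test_two_by_two_hand_enumeration(self):
        # [[0,1],[0,1]] at distance 1, angle 0: P(0,1)=P(1,0)=0.5
        cfg = TextureConfig(glcm_angles_deg=(0.0,), glcm_levels=2)
        out = glcm_features(np.array([[0.0, 1.0], [0.0, 1.0]]), cfg)
        contrast, dissim, homog = out[0], out[1], out[2]
        assert contrast == pytest.approx(1.0)
        assert dissim == pytest.approx(1.0)
        assert homog == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        image = rng.random((12, 14))
        cfg = TextureConfig(glcm_levels=8)
        expected = oracle_glcm(image, 8, 1, cfg.glcm_angles_deg)
        np.testing.assert_allclose(glcm_features(image, cfg), expected, atol=1e-10)

    def test_degenerate_single_pixel_raises(self):
        with pytest.raises(ValueError, match="too small"):
            glcm_features(np.array([[1.0]]))


class TestLBP:
    def test_returns_exactly_ten_values(self):
        rng = np.random.default_rng(0)
        assert len(lbp_features(rng.random((9, 9)))) == 10

    def test_constant_image_all_mass_in_full_ones_bin(self):
        hist = lbp_features(np.full((10, 10), 0.5))
        assert hist[8] == pytest.approx(1.0)
        assert hist.sum() == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_histogram_is_a_distribution(self, seed):
        image = np.random.default_rng(seed).random((8, 8))
        hist = lbp_features(image)
        assert np.all(hist >= 0)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)


class TestFourier:
    def test_zero_image(self):
        out = fourier_features(np.zeros((8, 8)))
        assert out[0] == 0.0 and out[1] == 0.0
        assert len(out) == 4

    def test_parseval_identity(self):
        image = np.random.default_rng(1).random((16, 12))
        spectrum_power = np.sum(np.abs(np.fft.fft2(image)) ** 2)
        assert spectrum_power == pytest.approx(image.size * np.sum(image ** 2), rel=1e-10)
        # and the reported magnitude stats are consistent with that spectrum
        mag = np.abs(np.fft.fft2(image))
        out = fourier_features(image)
        assert out[0] == pytest.approx(mag.mean())
        assert out[1] == pytest.approx(mag.std())


class TestGabor:
    SMALL = TextureConfig(gabor_wavelengths=(3.0, 4.0, 6.0, 8.0))

    def test_forty_eight_values_and_zero_image(self):
        out = gabor_features(np.zeros((24, 24)), self.SMALL)
        assert len(out) == 48
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matched_grating_beats_orthogonal_filter(self):
        wl = 8.0
        cfg = TextureConfig(gabor_wavelengths=(wl,), gabor_orientations_deg=(0.0, 90.0))
        yy, xx = np.mgrid[0:48, 0:48]
        grating = np.sin(2 * np.pi * xx / wl)  # varies along x
        out = gabor_features(grating, cfg)
        energy_0, energy_90 = out[2], out[5]
        assert energy_0 > energy_90

    def test_kernel_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="larger than image"):
            gabor_features(np.zeros((8, 8)), TextureConfig())


class TestWavelet:
    def test_twelve_values_constant_image_no_detail(self):
        out = wavelet_features(np.full((8, 8), 2.0))
        assert len(out) == 12
        # LH, HL, HH energies (indices 3, 6, 9) are zero
        assert out[3] == pytest.approx(0.0, abs=1e-20)
        assert out[6] == pytest.approx(0.0, abs=1e-20)
        assert out[9] == pytest.approx(0.0, abs=1e-20)

    def test_haar_energy_conservation(self):
        image = np.random.default_rng(2).random((16, 16))
        out = wavelet_features(image)
        subband_energy = out[0] + out[3] + out[6] + out[9]
        assert subband_energy == pytest.approx(np.sum(image ** 2), rel=1e-8)


class TestSpectralMeans:
    def test_background_excluded(self):
        crops = {b: np.where(np.eye(4, dtype=bool), 0.5, 0.0) for b in BAND_ORDER}
        masks = {b: np.eye(4, dtype=bool) for b in BAND_ORDER}
        np.testing.assert_allclose(spectral_means(crops, masks), 0.5)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        crops, masks = {}, {}
        expected = []
        for b in BAND_ORDER:
            img = rng.random((10, 10))
            m = rng.random((10, 10)) > 0.4
            m[0, 0] = True
            img[~m] = 0.0
            crops[b], masks[b] = img, m
            expected.append(sum(img[r, c] for r in range(10) for c in range(10)
                                if m[r, c]) / m.sum())
        np.testing.assert_allclose(spectral_means(crops, masks), expected)

    def test_all_background_band_raises(self):
        crops = {b: np.zeros((4, 4)) for b in BAND_ORDER}
        masks = {b: np.ones((4, 4), dtype=bool) for b in BAND_ORDER}
        masks["red"] = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="red"):
            spectral_means(crops, masks)


class TestExtractAll:
    def test_480_features_474_texture(self, calibrated_leaf):
        capture, gt = calibrated_leaf
        vec = extract_all(capture, gt.mask)
        assert len(vec) == 480
        assert len(texture_feature_names()) == 474
        assert vec.index.is_unique
        assert list(vec.index) == feature_names()
        assert np.all(np.isfinite(vec.to_numpy()))

    def test_per_band_texture_count_is_79(self):
        assert TextureConfig().n_texture_per_band() == 79
        per_band = [n for n in texture_feature_names() if n.startswith("green.")]
        assert len(per_band) == 79

    def test_deterministic(self, calibrated_leaf):
        capture, gt = calibrated_leaf
        a = extract_all(capture, gt.mask)
        b = extract_all(capture, gt.mask)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_invariant_to_background_padding(self, calibrated_leaf):
        # tight-bbox cropping makes features independent of surrounding scene
        from dataclasses import replace

        from leafchem.msio import MultispectralCapture

        capture, gt = calibrated_leaf
        padded_bands = {}
        for name, band in capture.bands.items():
            p = 8 if name != "pan" else 16
            padded_bands[name] = replace(
                band, pixels=np.pad(band.pixels, ((p, p), (p, p))))
        padded = MultispectralCapture(padded_bands, capture_id="padded")
        padded_mask = np.pad(gt.mask, ((8, 8), (8, 8)))
        a = extract_all(capture, gt.mask)
        b = extract_all(padded, padded_mask)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-10)
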