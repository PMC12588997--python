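"""Spectral + texture feature bank: 6 band means + 474 texture features.

Per leaf, for each of the six bands, the arithmetic mean reflectance over the
leaf mask (background excluded) plus 79 texture features computed on the
bounding-box crop with the background zeroed:

==============  ==  =============================================================
method           n  features
==============  ==  =============================================================
GLCM             5  contrast, dissimilarity, homogeneity, energy, correlation
LBP             10  rotation-invariant uniform (P=8, R=1) pattern histogram
Fourier          4  mean/std of the magnitude and phase spectra
Gabor           48  mean/std/energy for 4 wavelengths x 4 orientations
Wavelet         12  energy/variance/entropy for the LL, LH, HL, HH sub-bands
==============  ==  =============================================================

Total: 6 + 6 x 79 = 480 features with stable canonical names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from skimage.filters import gabor_kernel

from leafchem.msio import BAND_ORDER, MultispectralCapture
from leafchem.segblocks.extract import extract_leaf

GLCM_STATS = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation")
WAVELET_SUBBANDS = ("ll", "lh", "hl", "hh")
WAVELET_STATS = ("energy", "variance", "entropy")
GABOR_STATS = ("mean", "std", "energy")


@dataclass
class TextureConfig:
    """Defaults reproduce exactly 79 texture features per band."""

    glcm_distances: tuple[int, ...] = (1,)
    glcm_angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    glcm_levels: int = 32
    lbp_radius: int = 1
    lbp_points: int = 8
    gabor_wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0)
    gabor_orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gabor_sigma_ratio: float = 0.25  # sigma = ratio * wavelength
    gabor_n_stds: float = 2.0
    wavelet_family: str = "haar"

    def n_texture_per_band(self) -> int:
        return (len(GLCM_STATS) + (self.lbp_points + 2) + 4
                + len(self.gabor_wavelengths) * len(self.gabor_orientations_deg) * 3
                + 4 * 3)


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization to ``levels`` gray levels (constant image -> all 0)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1).astype(np.uint8)


def glcm_features(image: np.ndarray, cfg: TextureConfig | None = None) -> np.ndarray:
    """Contrast, dissimilarity, homogeneity, energy, correlation.

    The co-occurrence matrix is symmetric, normalized, and averaged over the
    configured distances and angles.  Energy is the square root of the
    angular second moment.  A constant image has, by convention, contrast 0,
    dissimilarity 0, homogeneity 1, energy 1 and correlation 1.
    """
    cfg = cfg or TextureConfig()
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) <= max(cfg.glcm_distances):
        raise ValueError("image too small for the configured GLCM distances")
    if np.ptp(image) == 0:
        return np.array([0.0, 0.0, 1.0, 1.0, 1.0])
    q = quantize(image, cfg.glcm_levels)
    angles = [np.deg2rad(a) for a in cfg.glcm_angles_deg]
    glcm = graycomatrix(q, distances=list(cfg.glcm_distances), angles=angles,
                        levels=cfg.glcm_levels, symmetric=True, normed=True)
    return np.array([float(np.mean(graycoprops(glcm, s))) for s in GLCM_STATS])


def lbp_features(image: np.ndarray, cfg: TextureConfig | None = None) -> np.ndarray:
    """Normalized 10-bin rotation-invariant uniform LBP histogram (P=8, R=1).

    With 8 neighbors the uniform patterns fall into P+2 = 10 classes: ten
    statistical features per image.
    """
    cfg = cfg or TextureConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("LBP needs an image of at least 3x3 pixels")
    # 8-bit min-max quantization: LBP compares neighbor order, and integer
    # codes avoid float-tie artifacts
    codes = local_binary_pattern(quantize(image, 256), P=cfg.lbp_points,
                                 R=cfg.lbp_radius, method="uniform")
    n_bins = cfg.lbp_points + 2
    hist, _ = np.histogram(codes, bins=np.arange(n_bins + 1) - 0.5)
    return hist / hist.sum()


def fourier_features(image: np.ndarray) -> np.ndarray:
    """Mean/std of the 2-D DFT magnitude and phase spectra (unshifted)."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    spectrum = np.fft.fft2(image)
    mag = np.abs(spectrum)
    phase = np.angle(spectrum)
    return np.array([mag.mean(), mag.std(), phase.mean(), phase.std()])


def gabor_bank(cfg: TextureConfig) -> list[tuple[str, np.ndarray]]:
    """Complex Gabor kernels, wavelength-major then orientation."""
    bank = []
    for wl in cfg.gabor_wavelengths:
        sigma = cfg.gabor_sigma_ratio * wl
        for deg in cfg.gabor_orientations_deg:
            kern = gabor_kernel(frequency=1.0 / wl, theta=np.deg2rad(deg),
                                sigma_x=sigma, sigma_y=sigma, n_stds=cfg.gabor_n_stds)
            bank.append((f"s{wl:g}_o{deg:g}", np.asarray(kern)))
    return bank


def gabor_features(image: np.ndarray, cfg: TextureConfig | None = None) -> np.ndarray:
    """Mean, std and energy of the response magnitude for each of 16 filters."""
    cfg = cfg or TextureConfig()
    image = np.asarray(image, dtype=np.float64)
    out = []
    for _, kern in gabor_bank(cfg):
        if kern.shape[0] > image.shape[0] or kern.shape[1] > image.shape[1]:
            raise ValueError(
                f"Gabor kernel {kern.shape} larger than image {image.shape}; "
                "reduce gabor_wavelengths or use a larger crop"
            )
        resp = fftconvolve(image, kern, mode="same")
        mag = np.abs(resp)
        out.extend([mag.mean(), mag.std(), float(np.sum(mag ** 2))])
    return np.array(out)


def wavelet_features(image: np.ndarray, cfg: TextureConfig | None = None) -> np.ndarray:
    """Energy, variance and Shannon entropy of the LL/LH/HL/HH sub-bands.

    Single-level 2-D decomposition; entropy is over the normalized
    squared-coefficient distribution, log base 2 with 0*log0 := 0.
    """
    cfg = cfg or TextureConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("wavelet decomposition needs at least 2x2 pixels")
    ll, (lh, hl, hh) = pywt.dwt2(image, cfg.wavelet_family)
    out = []
    for band in (ll, lh, hl, hh):
        c2 = band.ravel() ** 2
        energy = float(c2.sum())
        if energy > 0:
            p = c2 / energy
            nz = p[p > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
        else:
            entropy = 0.0
        out.extend([energy, float(np.var(band)), entropy])
    return np.array(out)


def spectral_means(crops: dict[str, np.ndarray], masks: dict[str, np.ndarray]) -> np.ndarray:
    """Per band, the mean over valid (leaf) pixels; background never counted."""
    out = []
    for band in BAND_ORDER:
        mask = np.asarray(masks[band], dtype=bool)
        if not mask.any():
            raise ValueError(f"band {band!r}: no valid leaf pixels")
        out.append(float(np.asarray(crops[band], dtype=np.float64)[mask].mean()))
    return np.array(out)


def texture_feature_names(cfg: TextureConfig | None = None) -> list[str]:
    cfg = cfg or TextureConfig()
    names = []
    for band in BAND_ORDER:
        names.extend(f"{band}.glcm.{s}" for s in GLCM_STATS)
        names.extend(f"{band}.lbp.bin{i:02d}" for i in range(cfg.lbp_points + 2))
        names.extend(f"{band}.fourier.{s}" for s in ("mag_mean", "mag_std", "phase_mean", "phase_std"))
        for wl in cfg.gabor_wavelengths:
            for deg in cfg.gabor_orientations_deg:
                names.extend(f"{band}.gabor.s{wl:g}_o{deg:g}.{s}" for s in GABOR_STATS)
        for sub in WAVELET_SUBBANDS:
            names.extend(f"{band}.wavelet.{sub}.{s}" for s in WAVELET_STATS)
    return names


def feature_names(cfg: TextureConfig | None = None) -> list[str]:
    """All 480 canonical names: 6 spectral means then 474 texture features."""
    return [f"band_mean.{b}" for b in BAND_ORDER] + texture_feature_names(cfg)


def band_texture_features(crop: np.ndarray, cfg: TextureConfig, band: str) -> np.ndarray:
    """The 79 texture features of one band crop, in canonical order."""
    parts = []
    for method, fn in (("glcm", glcm_features), ("lbp", lbp_features),
                       ("fourier", lambda im, _c: fourier_features(im)),
                       ("gabor", gabor_features), ("wavelet", wavelet_features)):
        try:
            parts.append(np.asarray(fn(crop, cfg)))
        except Exception as exc:  # noqa: BLE001 - reraise with band+method context
            raise ValueError(f"texture extraction failed for band {band!r}, method "
                             f"{method!r}: {exc}") from exc
    return np.concatenate(parts)


def extract_all(capture: MultispectralCapture, mask: np.ndarray,
                cfg: TextureConfig | None = None) -> pd.Series:
    """The full 480-feature vector for one leaf of a calibrated capture.

    The leaf is cropped to its tight bounding box per band (pan via 2x
    nearest-neighbor mask upsampling) with background zeroed; texture is
    computed on that crop, so features are unchanged by padding the scene
    with more background.
    """
    cfg = cfg or TextureConfig()
    crops, valid = extract_leaf(capture, mask)
    values = [spectral_means(crops, valid)]
    # small leaves: zero-pad the crop to the filter bank's minimum support
    # (background is zero anyway, so padding only extends it)
    support = max(max(k.shape) for _, k in gabor_bank(cfg))
    for band in BAND_ORDER:
        crop = crops[band]
        pr = max(0, support - crop.shape[0])
        pc = max(0, support - crop.shape[1])
        if pr or pc:
            crop = np.pad(crop, ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)))
        values.append(band_texture_features(crop, cfg, band))
    vec = pd.Series(np.concatenate(values), index=feature_names(cfg))
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise ValueError(f"non-finite features: {bad[:5]}")
    return vec


def features_table(rows: list[pd.Series], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack per-leaf feature vectors into a table, optionally with id columns."""
    table = pd.DataFrame(rows).reset_index(drop=True)
    if meta is not None:
        table = pd.concat([meta.reset_index(drop=True), table], axis=1)
    return table
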