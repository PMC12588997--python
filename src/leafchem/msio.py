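"""Multiband capture I/O and radiometric calibration.

A capture is a set of six co-registered single-band grayscale images from a
six-lens multispectral camera: blue (475 nm), green (560 nm), red (668 nm),
red-edge (717 nm), near-infrared (842 nm) and a wide panchromatic band
(634.5 nm) imaged at twice the spatial resolution of the narrow bands.

Pixel coordinates are row-major, 0-based, origin top-left; rectangles are
half-open ``[r0, r1) x [c0, c1)``.  Raw sensor output is in digital numbers
(DN); :func:`empirical_line_calibrate` converts DN to reflectance in [0, 1]
with a one-point empirical line anchored on a reference panel of known
reflectance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import tifffile
import yaml

#: Canonical band metadata: name -> (center wavelength nm, bandwidth nm).
BAND_INFO: dict[str, tuple[float, float]] = {
    "blue": (475.0, 32.0),
    "green": (560.0, 27.0),
    "red": (668.0, 16.0),
    "red_edge": (717.0, 12.0),
    "nir": (842.0, 57.0),
    "pan": (634.5, 463.0),
}

#: Fixed band order used everywhere features or files are enumerated.
BAND_ORDER: tuple[str, ...] = ("blue", "green", "red", "red_edge", "nir", "pan")


@dataclass
class BandImage:
    """One single-band grayscale image plus its spectral metadata."""

    pixels: np.ndarray
    band_name: str
    center_wavelength: float
    bandwidth: float
    units: str = "raw-DN"  # "raw-DN" | "reflectance"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"band {self.band_name!r}: pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError(f"band {self.band_name!r}: negative pixel values")
        if self.units == "reflectance" and self.pixels.size and float(self.pixels.max()) > 1.0 + 1e-9:
            raise ValueError(f"band {self.band_name!r}: reflectance values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class MultispectralCapture:
    """Six co-registered band images keyed by band name."""

    bands: dict[str, BandImage]
    capture_id: str = ""

    def __post_init__(self) -> None:
        missing = [b for b in BAND_ORDER if b not in self.bands]
        if missing:
            raise ValueError(f"capture {self.capture_id!r}: missing bands {missing}")
        shapes = {name: self.bands[name].shape for name in BAND_ORDER if name != "pan"}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"non-pan bands disagree in shape: {shapes}")

    @property
    def units(self) -> str:
        return self.bands[BAND_ORDER[0]].units

    @property
    def base_shape(self) -> tuple[int, int]:
        """Shape shared by the five narrow bands (pan may be 2x per axis)."""
        return self.bands["blue"].shape

    def band_array(self, name: str) -> np.ndarray:
        return self.bands[name].pixels


@dataclass
class CalibrationPanel:
    """Reference panel: image rectangle + per-band known reflectance.

    ``panel_region`` is ``(r0, r1, c0, c1)`` half-open in non-pan pixel
    coordinates; for the pan band the region is scaled by 2.
    """

    panel_region: tuple[int, int, int, int]
    known_reflectance: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.5 for b in BAND_ORDER}
    )

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.panel_region
        if r1 <= r0 or c1 <= c0:
            raise ValueError("panel_region is empty")
        for band, refl in self.known_reflectance.items():
            if not 0.0 < refl <= 1.0:
                raise ValueError(f"known reflectance of {band!r} must be in (0, 1], got {refl}")

    def region_for(self, band_name: str) -> tuple[int, int, int, int]:
        r0, r1, c0, c1 = self.panel_region
        if band_name == "pan":
            return 2 * r0, 2 * r1, 2 * c0, 2 * c1
        return r0, r1, c0, c1


def band_path(directory: str, plant: str | int, view: str | int, band: str) -> str:
    """Canonical per-band filename ``{plant}_{view}_{band}.tif``."""
    return os.path.join(directory, f"{plant}_{view}_{band}.tif")


def write_capture(capture: MultispectralCapture, directory: str, plant: str | int, view: str | int) -> list[str]:
    """Write one TIFF per band; returns the file paths in band order."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for band in BAND_ORDER:
        path = band_path(directory, plant, view, band)
        arr = capture.bands[band].pixels
        tifffile.imwrite(path, arr.astype(np.float32) if arr.dtype.kind == "f" else arr)
        paths.append(path)
    return paths


def read_capture(paths: Mapping[str, str] | str, plant: str | int = None, view: str | int = None,
                 units: str = "raw-DN", capture_id: str = "") -> MultispectralCapture:
    """Read a six-band capture.

    Parameters
    ----------
    paths
        Either a mapping ``band name -> file path`` or a directory; with a
        directory, ``plant`` and ``view`` select files via the canonical
        ``{plant}_{view}_{band}.tif`` pattern.
    """
    if isinstance(paths, str):
        if plant is None or view is None:
            raise ValueError("reading from a directory requires plant and view ids")
        paths = {b: band_path(paths, plant, view, b) for b in BAND_ORDER}
    missing = [b for b in BAND_ORDER if b not in paths or not os.path.exists(paths[b])]
    if missing:
        raise FileNotFoundError(f"missing band file(s): {missing}")
    bands = {}
    for b in BAND_ORDER:
        cw, bw = BAND_INFO[b]
        bands[b] = BandImage(tifffile.imread(paths[b]), b, cw, bw, units=units)
    return MultispectralCapture(bands, capture_id=capture_id)


def empirical_line_calibrate(capture: MultispectralCapture, panel: CalibrationPanel) -> MultispectralCapture:
    """One-point empirical-line calibration: DN -> reflectance.

    Per band, ``reflectance = DN * known_reflectance / mean(panel DN)``,
    clipped to [0, 1].  The transform is linear and order-preserving, and the
    panel pixels themselves map to the known reflectance on average.

    Raises if the capture is already in reflectance units (double scaling
    guard) or if the panel signal is zero in any band.
    """
    if capture.units == "reflectance":
        raise ValueError("capture is already calibrated to reflectance")
    h, w = capture.base_shape
    r0, r1, c0, c1 = panel.panel_region
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"panel region {panel.panel_region} outside image of shape {(h, w)}")
    out = {}
    for band in BAND_ORDER:
        img = capture.bands[band]
        pr0, pr1, pc0, pc1 = panel.region_for(band)
        panel_dn = float(np.mean(np.asarray(img.pixels, dtype=np.float64)[pr0:pr1, pc0:pc1]))
        if panel_dn <= 0:
            raise ValueError(f"zero panel signal in band {band!r}")
        gain = panel.known_reflectance[band] / panel_dn
        refl = np.clip(np.asarray(img.pixels, dtype=np.float64) * gain, 0.0, 1.0)
        out[band] = replace(img, pixels=refl.astype(np.float32), units="reflectance")
    return MultispectralCapture(out, capture_id=capture.capture_id)


def load_panel(path: str) -> CalibrationPanel:
    """Load a panel definition from YAML: {region: [r0,r1,c0,c1], reflectance: {band: value}}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return CalibrationPanel(tuple(cfg["region"]), dict(cfg["reflectance"]))


def save_panel(panel: CalibrationPanel, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"region": list(panel.panel_region), "reflectance": dict(panel.known_reflectance)}, fh
        )
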