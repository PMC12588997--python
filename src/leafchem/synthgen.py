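"""Synthetic multispectral leaf/plant scene generator.

Emulates a six-band multispectral acquisition campaign at two scales:

* **single-leaf captures** — one leaf on a dark laboratory background, with a
  reflectance reference panel in the frame;
* **plant scenes** — several leaves arranged along a vertical stem over
  soil-like clutter, with controlled pairwise occlusion and front-leaf-wins
  instance masks.

Chemistry is encoded so the downstream regressors have a recoverable signal
with the structure reported for real tobacco leaves:

* **nitrogen** raises base leaf reflectance in every band, with the largest
  slopes in the NIR and green bands, and additionally raises the spatial
  frequency of the vein texture (nitrogen affects both chlorophyll-driven
  reflectance and leaf structure);
* **nicotine** is encoded *only* in the vein-contrast amplitude, never in the
  band means — no spectral feature alone carries a strong nicotine signal;
* within a plant, expected nitrogen increases from the bottom leaf to the top
  while expected nicotine decreases (the canonical vertical gradient).

A per-leaf multiplicative illumination jitter perturbs all bands of a leaf
coherently, which limits what band means alone can recover and is the reason
texture features add information.

All randomness flows from ``SceneSpec.seed``: the same spec produces
bit-identical imagery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from leafchem.msio import (
    BAND_INFO,
    BAND_ORDER,
    BandImage,
    CalibrationPanel,
    MultispectralCapture,
    save_panel,
    write_capture,
)

# Base leaf reflectance per band: intercept + slope * nitrogen(%).
# Slopes are largest for NIR and green so that those bands correlate most
# strongly with nitrogen.
REFLECTANCE_MODEL: dict[str, tuple[float, float]] = {
    "blue": (0.10, 0.008),
    "green": (0.25, 0.040),
    "red": (0.15, 0.010),
    "red_edge": (0.35, 0.025),
    "nir": (0.45, 0.050),
    "pan": (0.20, 0.020),
}

# Soil reflectance level per band for plant-scene backgrounds.
SOIL_BASE: dict[str, float] = {
    "blue": 0.06, "green": 0.08, "red": 0.12, "red_edge": 0.16, "nir": 0.22, "pan": 0.12,
}

#: Chemistry bounds accepted by the generator (mass fraction, %).
CHEM_RANGE = (0.5, 5.0)


def vein_frequency(nitrogen: float) -> float:
    """Vein-texture spatial frequency (cycles across the leaf) vs nitrogen %."""
    return 6.0 + 2.0 * nitrogen


def vein_amplitude(nicotine: float) -> float:
    """Relative vein-contrast amplitude vs nicotine %."""
    return 0.04 * nicotine


def base_reflectance(band: str, nitrogen: float) -> float:
    """Noise-free leaf base reflectance for a band at a nitrogen content."""
    b0, b1 = REFLECTANCE_MODEL[band]
    return float(np.clip(b0 + b1 * nitrogen, 0.0, 1.0))


@dataclass
class BandDef:
    name: str
    center_wavelength: float
    bandwidth: float
    width: int
    height: int


def default_band_set(width: int = 256, height: int = 192) -> list[BandDef]:
    """Six camera bands; pan at twice the resolution of the narrow bands."""
    out = []
    for name in BAND_ORDER:
        cw, bw = BAND_INFO[name]
        scale = 2 if name == "pan" else 1
        out.append(BandDef(name, cw, bw, width * scale, height * scale))
    return out


@dataclass
class SceneSpec:
    """Full description of a synthetic acquisition campaign.

    The canvas default (256x192 for the narrow bands) is a working scale for
    tests and examples; pass ``width=2064, height=1544`` to emulate the real
    sensor resolution.
    """

    n_plants: int = 13
    views_per_plant: int = 3
    leaves_per_plant: tuple[int, int] = (5, 7)
    width: int = 256
    height: int = 192
    band_set: list[BandDef] = None  # type: ignore[assignment]
    overlap_fraction: float = 0.25
    background_clutter: float = 0.3
    seed: int = 0
    # imaging model
    noise_sigma: float = 0.01          # band-wise Gaussian noise, reflectance units
    illumination_jitter: float = 0.02  # sd of per-leaf multiplicative gain
    gains: dict[str, float] = field(default_factory=lambda: {b: 10000.0 for b in BAND_ORDER})
    panel_fraction: float = 0.10       # panel side as a fraction of canvas height
    panel_reflectance: float = 0.5
    # chemistry model
    nitrogen_range: tuple[float, float] = (1.5, 4.5)
    nicotine_range: tuple[float, float] = (1.5, 3.5)
    chem_noise: float = 0.05           # sd of per-leaf deviation from the gradient

    def __post_init__(self) -> None:
        if self.band_set is None:
            self.band_set = default_band_set(self.width, self.height)
        if len(self.band_set) != 6:
            raise ValueError("band_set must have exactly 6 entries")
        names = [b.name for b in self.band_set]
        if set(names) != set(BAND_ORDER):
            raise ValueError(f"band_set names must be {BAND_ORDER}, got {names}")
        for b in self.band_set:
            ref = next(d for d in default_band_set(self.width, self.height) if d.name == b.name)
            if (b.width, b.height) != (ref.width, ref.height):
                raise ValueError(f"band {b.name}: expected {ref.width}x{ref.height} (pan is 2x)")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")

    @property
    def panel_region(self) -> tuple[int, int, int, int]:
        """Panel rectangle (r0, r1, c0, c1) in narrow-band pixel coordinates."""
        side = max(4, int(round(self.panel_fraction * self.height)))
        return (2, 2 + side, 2, 2 + side)

    def panel(self) -> CalibrationPanel:
        return CalibrationPanel(self.panel_region,
                                {b: self.panel_reflectance for b in BAND_ORDER})


@dataclass
class GroundTruth:
    """Per-leaf ground truth: identity, canopy position, chemistry, mask."""

    leaf_id: str
    plant_id: int
    view_id: int
    position_index: int  # 1 = bottom leaf
    nitrogen: float
    nicotine: float
    mask: np.ndarray     # bool, narrow-band resolution, visible (occluded) part


@dataclass
class _LeafGeom:
    """Leaf geometry in fractional canvas coordinates (resolution independent)."""

    cx: float
    cy: float
    angle: float       # radians, major-axis direction
    a: float           # semi-major, fraction of canvas height
    b: float           # semi-minor, fraction of canvas height
    lobe_amp: float
    lobe_k: int
    lobe_phase: float
    nitrogen: float
    nicotine: float
    illum: float
    tex_phase: float


def _leaf_coords(geom: _LeafGeom, width: int, height: int):
    """Return (inside-mask, u, v): u along the major axis in [-1,1], v across."""
    yy, xx = np.mgrid[0:height, 0:width]
    x = xx / height - geom.cx   # normalize both axes by height -> isotropic
    y = yy / height - geom.cy
    ca, sa = np.cos(geom.angle), np.sin(geom.angle)
    u = (x * ca + y * sa) / geom.a
    v = (-x * sa + y * ca) / geom.b
    theta = np.arctan2(v, u)
    boundary = 1.0 + geom.lobe_amp * np.cos(geom.lobe_k * theta + geom.lobe_phase)
    inside = u * u + v * v <= boundary * boundary
    return inside, u, v


def _leaf_texture(geom: _LeafGeom, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Zero-centred vein texture field; amplitude from nicotine, frequency from nitrogen."""
    f = vein_frequency(geom.nitrogen)
    amp = vein_amplitude(geom.nicotine)
    phase = 2.0 * np.pi * f * (0.5 * (u + 1.0) + 0.25 * np.abs(v)) + geom.tex_phase
    return amp * np.cos(phase)


def _smooth_field(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Low-frequency clutter field in [0, 1], consistent across render scales."""
    coarse = rng.random((12, 16))
    field_img = ndimage.zoom(coarse, (height / 12, width / 16), order=1, grid_mode=True,
                             mode="nearest")
    field_img = field_img[:height, :width]
    lo, hi = field_img.min(), field_img.max()
    return (field_img - lo) / (hi - lo + 1e-12)


def _render(spec: SceneSpec, leaves: Sequence[_LeafGeom], clutter_coarse: np.ndarray | None,
            lab_background: bool, scale: int) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Render noise-free reflectance per band plus the instance label image.

    Later leaves in ``leaves`` are drawn on top (front-leaf-wins).  ``scale``
    is 1 for the narrow bands and 2 for pan.
    """
    w, h = spec.width * scale, spec.height * scale
    if lab_background:
        background = {band: np.full((h, w), 0.02, dtype=np.float64) for band in BAND_ORDER}
    else:
        if clutter_coarse is None:
            raise ValueError("plant scenes need a clutter field")
        field_img = ndimage.zoom(clutter_coarse, (h / clutter_coarse.shape[0],
                                                  w / clutter_coarse.shape[1]),
                                 order=1, mode="nearest")[:h, :w]
        background = {
            band: SOIL_BASE[band] * (0.7 + 0.6 * spec.background_clutter * field_img)
            for band in BAND_ORDER
        }
    label = np.zeros((h, w), dtype=np.uint16)
    refl = background
    for idx, geom in enumerate(leaves, start=1):
        inside, u, v = _leaf_coords(geom, w, h)
        tex = _leaf_texture(geom, u, v)
        label[inside] = idx
        for band in BAND_ORDER:
            base = base_reflectance(band, geom.nitrogen)
            leaf_refl = np.clip(base * (1.0 + tex) * geom.illum, 0.0, 1.0)
            refl[band] = np.where(inside, leaf_refl, refl[band])
    # calibration panel is never occluded
    r0, r1, c0, c1 = spec.panel_region
    r0, r1, c0, c1 = r0 * scale, r1 * scale, c0 * scale, c1 * scale
    for band in BAND_ORDER:
        refl[band][r0:r1, c0:c1] = spec.panel_reflectance
    label[r0:r1, c0:c1] = 0
    return refl, label


def _to_capture(spec: SceneSpec, refl_1x: dict[str, np.ndarray],
                refl_2x: dict[str, np.ndarray], rng: np.random.Generator,
                capture_id: str) -> MultispectralCapture:
    """Apply band noise, convert reflectance to DN via per-band gain."""
    bands = {}
    for band in BAND_ORDER:
        base = refl_2x[band] if band == "pan" else refl_1x[band]
        noisy = base
        if spec.noise_sigma > 0:
            noisy = base + rng.normal(0.0, spec.noise_sigma, size=base.shape)
        dn = np.clip(noisy, 0.0, 1.0) * spec.gains[band]
        cw, bw = BAND_INFO[band]
        bands[band] = BandImage(dn.astype(np.float32), band, cw, bw, units="raw-DN")
    return MultispectralCapture(bands, capture_id=capture_id)


def _check_chemistry(nitrogen: float, nicotine: float) -> None:
    lo, hi = CHEM_RANGE
    for name, val in (("nitrogen", nitrogen), ("nicotine", nicotine)):
        if not lo <= val <= hi:
            raise ValueError(f"{name} = {val} outside the plausible range [{lo}, {hi}] %")


def generate_leaf_capture(spec: SceneSpec, chemistry: tuple[float, float],
                          leaf_id: str = "leaf", rng: np.random.Generator | None = None,
                          ) -> tuple[MultispectralCapture, GroundTruth]:
    """Render one laboratory single-leaf capture (dark background + panel).

    ``chemistry`` is ``(nitrogen %, nicotine %)``; values outside the
    plausible range are rejected.
    """
    nitrogen, nicotine = chemistry
    _check_chemistry(nitrogen, nicotine)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    illum = float(np.exp(rng.normal(0.0, spec.illumination_jitter)))
    geom = _LeafGeom(
        cx=0.70 * spec.width / spec.height, cy=0.52,
        angle=float(rng.uniform(-0.25, 0.25)),
        a=0.34, b=0.20,
        lobe_amp=0.06, lobe_k=5, lobe_phase=float(rng.uniform(0, 2 * np.pi)),
        nitrogen=nitrogen, nicotine=nicotine, illum=illum,
        tex_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    refl_1x, label_1x = _render(spec, [geom], None, lab_background=True, scale=1)
    refl_2x, _ = _render(spec, [geom], None, lab_background=True, scale=2)
    capture = _to_capture(spec, refl_1x, refl_2x, rng, capture_id=leaf_id)
    gt = GroundTruth(leaf_id=leaf_id, plant_id=-1, view_id=-1, position_index=1,
                     nitrogen=nitrogen, nicotine=nicotine, mask=label_1x == 1)
    return capture, gt


def chemistry_profile(spec: SceneSpec, n_leaves: int, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Expected (noise-free) per-position chemistry for one plant.

    Nitrogen rises linearly from a bottom value to a top value; nicotine
    falls.  Position 1 is the bottom leaf.
    """
    n_lo, n_hi = spec.nitrogen_range
    c_lo, c_hi = spec.nicotine_range
    nb = rng.uniform(n_lo, n_lo + 0.3 * (n_hi - n_lo))
    nt = rng.uniform(n_hi - 0.3 * (n_hi - n_lo), n_hi)
    cb = rng.uniform(c_hi - 0.3 * (c_hi - c_lo), c_hi)
    ct = rng.uniform(c_lo, c_lo + 0.3 * (c_hi - c_lo))
    t = np.linspace(0.0, 1.0, n_leaves) if n_leaves > 1 else np.array([0.5])
    return nb + (nt - nb) * t, cb + (ct - cb) * t


def _mask_overlap(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    return inter / min(np.count_nonzero(a), np.count_nonzero(b))


def _layout_plant(spec: SceneSpec, n_leaves: int, rng: np.random.Generator,
                  nitro: np.ndarray, nico: np.ndarray) -> list[_LeafGeom]:
    """Place leaves bottom-to-top along a stem, enforcing the overlap budget.

    Leaves alternate sides of the stem; each new leaf is pushed outwards until
    its overlap with every previously placed leaf is within
    ``spec.overlap_fraction`` (exactly disjoint when the budget is 0).
    """
    aspect = spec.width / spec.height
    min_span = 0.10
    if n_leaves < 1:
        raise ValueError("leaves_per_plant must be >= 1")
    if n_leaves * min_span > 0.95:
        raise ValueError(f"{n_leaves} leaves do not fit on a {spec.width}x{spec.height} canvas")
    stem_x = 0.58 * aspect
    ys = np.linspace(0.85, 0.22, n_leaves)
    geoms: list[_LeafGeom] = []
    masks: list[np.ndarray] = []
    for pos in range(n_leaves):
        side = 1 if pos % 2 == 0 else -1
        droop = rng.uniform(0.15, 0.45)
        base_offset = 0.13 if spec.overlap_fraction > 0 else 0.20
        geom = _LeafGeom(
            cx=stem_x + side * base_offset, cy=float(ys[pos]),
            angle=side * droop if side > 0 else np.pi - droop,
            a=float(rng.uniform(0.15, 0.19)), b=float(rng.uniform(0.085, 0.11)),
            lobe_amp=0.06, lobe_k=5, lobe_phase=float(rng.uniform(0, 2 * np.pi)),
            nitrogen=float(np.clip(nitro[pos] + rng.normal(0, spec.chem_noise), *CHEM_RANGE)),
            nicotine=float(np.clip(nico[pos] + rng.normal(0, spec.chem_noise), *CHEM_RANGE)),
            illum=float(np.exp(rng.normal(0.0, spec.illumination_jitter))),
            tex_phase=float(rng.uniform(0, 2 * np.pi)),
        )
        for _attempt in range(80):
            inside, _, _ = _leaf_coords(geom, spec.width, spec.height)
            r0, r1, c0, c1 = spec.panel_region
            panel_clear = not inside[r0:r1, c0:c1].any()
            ok = panel_clear and all(
                _mask_overlap(inside, m) <= spec.overlap_fraction for m in masks
            )
            if ok:
                break
            geom.cx += side * 0.015  # push outwards
        else:
            raise ValueError(
                f"impossible layout: cannot place leaf {pos + 1} of {n_leaves} within "
                f"overlap budget {spec.overlap_fraction}"
            )
        geoms.append(geom)
        masks.append(inside)
    return geoms


def generate_plant_scene(spec: SceneSpec, plant_id: int, view_id: int,
                         ) -> tuple[MultispectralCapture, list[GroundTruth]]:
    """Render one whole-plant view: several leaves over soil-like clutter.

    Leaves are drawn bottom first, so upper (later) leaves occlude lower ones
    and each visible mask is the front leaf at every pixel.  Chemistry follows
    the vertical gradient (nitrogen up, nicotine down) plus per-leaf noise.
    """
    rng = np.random.default_rng([spec.seed, plant_id, view_id])
    lo, hi = spec.leaves_per_plant
    n_leaves = int(rng.integers(lo, hi + 1))
    nitro, nico = chemistry_profile(spec, n_leaves, rng)
    geoms = _layout_plant(spec, n_leaves, rng, nitro, nico)
    clutter = rng.random((12, 16))
    refl_1x, label_1x = _render(spec, geoms, clutter, lab_background=False, scale=1)
    refl_2x, _ = _render(spec, geoms, clutter, lab_background=False, scale=2)
    cap_id = f"{plant_id}_{view_id}"
    capture = _to_capture(spec, refl_1x, refl_2x, rng, capture_id=cap_id)
    truths = [
        GroundTruth(leaf_id=f"{cap_id}_L{pos}", plant_id=plant_id, view_id=view_id,
                    position_index=pos, nitrogen=g.nitrogen, nicotine=g.nicotine,
                    mask=label_1x == pos)
        for pos, g in enumerate(geoms, start=1)
    ]
    return capture, truths


def write_label_png(label: np.ndarray, path: str) -> None:
    """Write a 16-bit instance label image (0 = background, k = instance k)."""
    Image.fromarray(label.astype(np.uint16)).save(path)


def read_label_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path)).astype(np.uint16)


def _label_from_truths(truths: Sequence[GroundTruth]) -> np.ndarray:
    label = np.zeros(truths[0].mask.shape, dtype=np.uint16)
    for t in truths:
        label[t.mask] = t.position_index
    return label


def generate_dataset(spec: SceneSpec, out_dir: str) -> pd.DataFrame:
    """Write the whole plant-scene campaign: band TIFFs, label PNGs, chemistry CSV.

    Emits ``n_plants x views_per_plant`` captures (6 band TIFFs each), one
    label PNG per capture, a ``chemistry.csv`` with one row per leaf, a panel
    definition YAML, and a ``manifest.csv`` with one row per capture.
    Re-running with the same spec reproduces every file exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_rows, chem_rows = [], []
    for plant in range(1, spec.n_plants + 1):
        for view in range(1, spec.views_per_plant + 1):
            capture, truths = generate_plant_scene(spec, plant, view)
            write_capture(capture, out_dir, plant, view)
            mask_path = os.path.join(out_dir, f"{plant}_{view}_mask.png")
            write_label_png(_label_from_truths(truths), mask_path)
            manifest_rows.append({
                "capture_id": capture.capture_id, "plant_id": plant, "view_id": view,
                "n_leaves": len(truths), "mask_path": os.path.basename(mask_path),
                **{f"band_{b}": f"{plant}_{view}_{b}.tif" for b in BAND_ORDER},
            })
            for t in truths:
                chem_rows.append({
                    "leaf_id": t.leaf_id, "plant_id": plant, "view_id": view,
                    "position_index": t.position_index,
                    "nitrogen": t.nitrogen, "nicotine": t.nicotine,
                })
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    pd.DataFrame(chem_rows).to_csv(os.path.join(out_dir, "chemistry.csv"), index=False)
    save_panel(spec.panel(), os.path.join(out_dir, "panel.yaml"))
    return manifest


def generate_leaf_dataset(spec: SceneSpec, out_dir: str, n_leaves: int = 120) -> pd.DataFrame:
    """Write a laboratory single-leaf campaign: ``n_leaves`` captures.

    Chemistry per leaf is drawn uniformly from the spec's ranges; with the
    default six bands this emits ``n_leaves * 6`` single-band images.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 941])
    manifest_rows, chem_rows = [], []
    for i in range(1, n_leaves + 1):
        nitrogen = float(rng.uniform(*spec.nitrogen_range))
        nicotine = float(rng.uniform(*spec.nicotine_range))
        leaf_id = f"leaf{i:04d}"
        capture, gt = generate_leaf_capture(spec, (nitrogen, nicotine), leaf_id=leaf_id, rng=rng)
        write_capture(capture, out_dir, leaf_id, 1)
        mask_path = os.path.join(out_dir, f"{leaf_id}_1_mask.png")
        write_label_png(gt.mask.astype(np.uint16), mask_path)
        manifest_rows.append({
            "capture_id": leaf_id, "plant_id": leaf_id, "view_id": 1, "n_leaves": 1,
            "mask_path": os.path.basename(mask_path),
            **{f"band_{b}": f"{leaf_id}_1_{b}.tif" for b in BAND_ORDER},
        })
        chem_rows.append({"leaf_id": leaf_id, "plant_id": leaf_id, "view_id": 1,
                          "position_index": 1, "nitrogen": nitrogen, "nicotine": nicotine})
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    pd.DataFrame(chem_rows).to_csv(os.path.join(out_dir, "chemistry.csv"), index=False)
    save_panel(spec.panel(), os.path.join(out_dir, "panel.yaml"))
    return manifest
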