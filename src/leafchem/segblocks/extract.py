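"""Mask-based leaf extraction: crop each leaf region, zero the background.

Extraction feeds the feature bank: for every band the leaf's tight bounding
box is cropped and all non-leaf pixels are set to 0, together with a
companion validity mask.  The pan band runs at twice the narrow-band
resolution; its mask is obtained by 2x nearest-neighbor upsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from leafchem.msio import BAND_ORDER, MultispectralCapture


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight bounding box (r0, r1, c0, c1), half-open, of the true pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass
class InstanceMask:
    """One predicted or ground-truth leaf instance."""

    leaf_id: str
    mask: np.ndarray
    score: float = 1.0
    bbox: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        tight = mask_bbox(self.mask)
        if self.bbox is None:
            self.bbox = tight
        elif tuple(self.bbox) != tight:
            raise ValueError(f"bbox {self.bbox} is not the tight box {tight} of the mask")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def upsample2x(mask: np.ndarray) -> np.ndarray:
    """2x nearest-neighbor upsampling of a boolean mask."""
    return np.repeat(np.repeat(np.asarray(mask, dtype=bool), 2, axis=0), 2, axis=1)


def extract_leaf(capture: MultispectralCapture, mask: np.ndarray | InstanceMask,
                 ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-band bounding-box crops with background zeroed, plus validity masks.

    The mask must match the narrow-band resolution; returns
    ``(crops, valid)`` keyed by band name.
    """
    if isinstance(mask, InstanceMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != capture.base_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match band shape {capture.base_shape}"
        )
    if not mask.any():
        raise ValueError("empty mask: nothing to extract")
    crops: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for band in BAND_ORDER:
        band_mask = upsample2x(mask) if capture.bands[band].shape != mask.shape else mask
        r0, r1, c0, c1 = mask_bbox(band_mask)
        sub_mask = band_mask[r0:r1, c0:c1]
        crop = np.array(capture.bands[band].pixels[r0:r1, c0:c1], dtype=np.float64)
        crop[~sub_mask] = 0.0
        crops[band] = crop
        valid[band] = sub_mask
    return crops, valid


def masks_from_coco(payload: dict | str, shape: tuple[int, int]) -> list[InstanceMask]:
    """Build instance masks from COCO-style polygon annotations.

    Each annotation needs a ``segmentation`` list of ``[x0, y0, x1, y1, ...]``
    polygons; ``score`` and ``id`` are optional.
    """
    from skimage.draw import polygon as sk_polygon

    if isinstance(payload, str):
        with open(payload) as fh:
            payload = json.load(fh)
    out = []
    for k, ann in enumerate(payload.get("annotations", [])):
        mask = np.zeros(shape, dtype=bool)
        for poly in ann["segmentation"]:
            xs = np.asarray(poly[0::2], dtype=float)
            ys = np.asarray(poly[1::2], dtype=float)
            rr, cc = sk_polygon(ys, xs, shape=shape)
            mask[rr, cc] = True
        out.append(InstanceMask(str(ann.get("id", k)), mask,
                                score=float(ann.get("score", 1.0))))
    return out
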