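"""Spatial rendering of predicted leaf chemistry over plant images.

Each leaf region is flood-filled (with configurable alpha) with the colormap
color of its predicted value; background pixels are untouched.  Rendering is
a pure function of (image, masks, values, colormap, range); the legend is
added when saving through matplotlib.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from leafchem.segblocks.extract import InstanceMask  # noqa: E402


def render_content_map(image: np.ndarray, masks: Sequence[np.ndarray | InstanceMask],
                       values: Sequence[float], colormap: str = "viridis",
                       value_range: tuple[float, float] | None = None,
                       alpha: float = 1.0) -> np.ndarray:
    """Overlay per-leaf predictions as flat colors; returns an RGB float image.

    ``image`` may be 2-D grayscale (any positive scale; normalized for
    display) or already RGB in [0, 1].  Values outside ``value_range`` are
    clipped with a warning.
    """
    if len(masks) != len(values):
        raise ValueError("every mask needs exactly one predicted value")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        lo, hi = img.min(), img.max()
        gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        rgb = np.stack([gray] * 3, axis=-1)
    else:
        rgb = img.copy()
    values = np.asarray(values, dtype=float)
    if value_range is None:
        value_range = (float(values.min()), float(values.max()))
    vmin, vmax = value_range
    if np.any(values < vmin) or np.any(values > vmax):
        warnings.warn(f"predictions outside value range {value_range}; clipped",
                      stacklevel=2)
        values = np.clip(values, vmin, vmax)
    cmap = matplotlib.colormaps[colormap]
    span = vmax - vmin or 1.0
    for mask, val in zip(masks, values):
        if isinstance(mask, InstanceMask):
            mask = mask.mask
        color = np.asarray(cmap((val - vmin) / span))[:3]
        rgb[mask] = (1.0 - alpha) * rgb[mask] + alpha * color
    return rgb


def save_content_map(rendered: np.ndarray, path: str, value_range: tuple[float, float],
                     colormap: str = "viridis", title: str = "",
                     label: str = "content (%)") -> None:
    """Write the rendered overlay to PNG with an embedded value-scale legend."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.imshow(rendered)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    sm = plt.cm.ScalarMappable(
        cmap=colormap, norm=plt.Normalize(vmin=value_range[0], vmax=value_range[1])
    )
    fig.colorbar(sm, ax=ax, fraction=0.04, pad=0.02, label=label)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
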