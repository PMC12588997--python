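"""Minimal NumPy convolution/activation primitives shared by the blocks.

Feature maps are ``(channels, height, width)`` float arrays; all convolutions
are stride 1 with zero padding chosen to preserve the spatial size.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Same-size 2-D convolution (cross-correlation) of a CHW map.

    ``kernel`` is ``(C_out, C_in, kh, kw)`` with odd kh, kw.
    """
    c_in, h, w = x.shape
    c_out, kc, kh, kw = kernel.shape
    if kc != c_in:
        raise ValueError(f"channel mismatch: input has {c_in}, kernel expects {kc}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (C_in, H, W, kh, kw)
    out = np.einsum("ihwkl,oikl->ohw", win, kernel, optimize=True)
    if bias is not None:
        out = out + bias[:, None, None]
    return out


def conv1x1(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Pointwise convolution; ``weight`` is ``(C_out, C_in)``."""
    out = np.tensordot(weight, x, axes=(1, 0))
    if bias is not None:
        out = out + bias[:, None, None]
    return out


def depthwise3x3(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Per-channel 3x3 convolution; ``kernels`` is ``(C, 3, 3)``."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))
    return np.einsum("ihwkl,ikl->ihw", win, kernels, optimize=True)


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def he_kernel(rng: np.random.Generator, c_out: int, c_in: int, k: int = 3) -> np.ndarray:
    scale = np.sqrt(2.0 / (c_in * k * k))
    return rng.normal(0.0, scale, size=(c_out, c_in, k, k))


def adaptive_avg_pool(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Pool a CHW map to (C, out_h, out_w) by averaging near-equal tiles."""
    c, h, w = x.shape
    if out_h > h or out_w > w:
        raise ValueError(f"pool size ({out_h}, {out_w}) exceeds map size ({h}, {w})")
    re = np.linspace(0, h, out_h + 1).round().astype(int)
    ce = np.linspace(0, w, out_w + 1).round().astype(int)
    out = np.empty((c, out_h, out_w), dtype=x.dtype)
    for i in range(out_h):
        for j in range(out_w):
            out[:, i, j] = x[:, re[i]:re[i + 1], ce[j]:ce[j + 1]].mean(axis=(1, 2))
    return out
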