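"""Dual-path aggregated attention.

Every query pixel attends jointly over two key sets:

* a fine-grained **local** path — the keys inside its ``window_size`` x
  ``window_size`` neighborhood (out-of-image positions are excluded from the
  softmax rather than attended as zeros);
* a coarse-grained **global** path — the whole feature map average-pooled to
  ``pool_size`` x ``pool_size`` keys shared by all queries.

The softmax normalizes over the union of both paths, so the weight vector of
each query sums to one.  Multi-head: channels are split evenly across heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from leafchem.segblocks.nn import adaptive_avg_pool


@dataclass
class AAConfig:
    channel_dim: int
    window_size: int = 3
    pool_size: int = 2
    n_heads: int = 2

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd integer >= 3")
        if self.channel_dim % self.n_heads != 0:
            raise ValueError(
                f"channel_dim {self.channel_dim} not divisible by n_heads {self.n_heads}"
            )


@dataclass
class AAParams:
    """Pointwise query/key/value/output projections, shared across heads."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray

    @classmethod
    def init(cls, cfg: AAConfig, rng: np.random.Generator) -> "AAParams":
        c = cfg.channel_dim
        s = 1.0 / np.sqrt(c)
        return cls(*(rng.normal(0.0, s, size=(c, c)) for _ in range(4)))

    @classmethod
    def identity(cls, cfg: AAConfig) -> "AAParams":
        eye = np.eye(cfg.channel_dim)
        return cls(eye.copy(), eye.copy(), eye.copy(), eye.copy())


def aggregated_attention(x: np.ndarray, cfg: AAConfig, params: AAParams,
                         return_weights: bool = False) -> np.ndarray:
    """Apply dual-path attention to a CHW feature map; output shape = input shape.

    With ``return_weights`` the per-query weight tensor
    ``(heads, H, W, window^2 + pool^2)`` is returned as a second value
    (padded local slots carry weight exactly 0).
    """
    c, h, w = x.shape
    if c != cfg.channel_dim:
        raise ValueError(f"expected {cfg.channel_dim} channels, got {c}")
    ws, ps = cfg.window_size, cfg.pool_size
    if min(h, w) < ws:
        raise ValueError(f"spatial dims {(h, w)} smaller than window {ws}")
    if ps > min(h, w):
        raise ValueError(f"pool_size {ps} exceeds spatial dims {(h, w)}")

    q = np.tensordot(params.wq, x, axes=(1, 0))
    k = np.tensordot(params.wk, x, axes=(1, 0))
    v = np.tensordot(params.wv, x, axes=(1, 0))
    kg = adaptive_avg_pool(k, ps, ps).reshape(c, ps * ps)
    vg = adaptive_avg_pool(v, ps, ps).reshape(c, ps * ps)

    pad = ws // 2
    kp = np.pad(k, ((0, 0), (pad, pad), (pad, pad)))
    vp = np.pad(v, ((0, 0), (pad, pad), (pad, pad)))
    k_win = sliding_window_view(kp, (ws, ws), axis=(1, 2))  # (C, H, W, ws, ws)
    v_win = sliding_window_view(vp, (ws, ws), axis=(1, 2))
    valid = sliding_window_view(
        np.pad(np.ones((h, w), dtype=bool), pad), (ws, ws), axis=(0, 1)
    ).reshape(h, w, ws * ws)

    n_heads, dh = cfg.n_heads, c // cfg.n_heads
    scale = 1.0 / np.sqrt(dh)
    out = np.empty_like(q)
    weights = np.empty((n_heads, h, w, ws * ws + ps * ps)) if return_weights else None
    for head in range(n_heads):
        sl = slice(head * dh, (head + 1) * dh)
        qh = q[sl]
        logits_local = np.einsum("chw,chwkl->hwkl", qh, k_win[sl], optimize=True)
        logits_local = logits_local.reshape(h, w, ws * ws) * scale
        logits_global = np.einsum("chw,cg->hwg", qh, kg[sl], optimize=True) * scale
        logits = np.concatenate([logits_local, logits_global], axis=-1)
        mask = np.concatenate(
            [valid, np.ones((h, w, ps * ps), dtype=bool)], axis=-1
        )
        logits = np.where(mask, logits, -np.inf)
        logits -= logits.max(axis=-1, keepdims=True)
        wgt = np.exp(logits)
        wgt /= wgt.sum(axis=-1, keepdims=True)
        if weights is not None:
            weights[head] = wgt
        v_all = np.concatenate(
            [v_win[sl].reshape(dh, h, w, ws * ws),
             np.broadcast_to(vg[sl][:, None, None, :], (dh, h, w, ps * ps))],
            axis=-1,
        )
        out[sl] = np.einsum("hwn,chwn->chw", wgt, v_all, optimize=True)
    result = np.tensordot(params.wo, out, axes=(1, 0))
    if return_weights:
        return result, weights  # type: ignore[return-value]
    return result
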