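"""C2f with aggregated attention (C2f_AA).

C2f is the cross-stage partial block: a pointwise expansion is split into two
halves, one half runs through a chain of residual 3x3 bottlenecks, every
intermediate result is concatenated and fused by a final pointwise
convolution.  C2f_AA applies the dual-path aggregated attention to the fused
features on top of the plain C2f computation, so with the attention replaced
by the identity the block reduces exactly to C2f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from leafchem.segblocks.attention import AAConfig, AAParams, aggregated_attention
from leafchem.segblocks.nn import conv1x1, conv2d, he_kernel, silu


@dataclass
class C2fConfig:
    c_in: int
    c_out: int
    n_bottlenecks: int = 2
    attention: AAConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.c_out % 2 != 0:
            raise ValueError("c_out must be even (channel split)")
        if self.attention is None:
            self.attention = AAConfig(channel_dim=self.c_out)
        if self.attention.channel_dim != self.c_out:
            raise ValueError("attention channel_dim must equal c_out")

    @property
    def c_hidden(self) -> int:
        return self.c_out // 2


@dataclass
class C2fAAParams:
    cv1: np.ndarray                       # (2*ch, c_in)
    bottlenecks: list[tuple[np.ndarray, np.ndarray]]  # pairs of (ch, ch, 3, 3)
    cv2: np.ndarray                       # (c_out, (2+n)*ch)
    attn: AAParams

    @classmethod
    def init(cls, cfg: C2fConfig, rng: np.random.Generator) -> "C2fAAParams":
        ch = cfg.c_hidden
        return cls(
            cv1=rng.normal(0, 1 / np.sqrt(cfg.c_in), (2 * ch, cfg.c_in)),
            bottlenecks=[(he_kernel(rng, ch, ch), he_kernel(rng, ch, ch))
                         for _ in range(cfg.n_bottlenecks)],
            cv2=rng.normal(0, 1 / np.sqrt((2 + cfg.n_bottlenecks) * ch),
                           (cfg.c_out, (2 + cfg.n_bottlenecks) * ch)),
            attn=AAParams.init(cfg.attention, rng),
        )


def c2f_forward(x: np.ndarray, cfg: C2fConfig, params: C2fAAParams) -> np.ndarray:
    """Plain C2f: split / residual bottlenecks / concat / pointwise fuse."""
    if x.shape[0] != cfg.c_in:
        raise ValueError(f"expected {cfg.c_in} channels, got {x.shape[0]}")
    ch = cfg.c_hidden
    y = silu(conv1x1(x, params.cv1))
    parts = [y[:ch], y[ch:]]
    for w1, w2 in params.bottlenecks:
        prev = parts[-1]
        parts.append(prev + conv2d(silu(conv2d(prev, w1)), w2))
    return silu(conv1x1(np.concatenate(parts, axis=0), params.cv2))


def c2f_aa_forward(x: np.ndarray, cfg: C2fConfig, params: C2fAAParams,
                   use_attention: bool = True) -> np.ndarray:
    """C2f with aggregated attention on the fused features.

    ``use_attention=False`` is the ablation switch: the output is then the
    plain C2f output.
    """
    fused = c2f_forward(x, cfg, params)
    if not use_attention:
        return fused
    return fused + aggregated_attention(fused, cfg.attention, params.attn)
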