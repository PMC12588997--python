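"""OREPAGELAN: a GELAN-style aggregation block whose convolution units are
six-branch OREPA blocks.

Topology: a pointwise transition splits the input into two halves; one half
runs through a chain of OREPA units (SiLU between units), every intermediate
result is kept, and all parts are concatenated and fused by a final pointwise
transition.  ``compress()`` swaps every OREPA unit to its folded single-conv
form; since folding is exact and the surrounding ops are unchanged, the block
output is preserved to float tolerance while the parameter count drops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from leafchem.segblocks.nn import conv1x1, silu
from leafchem.segblocks.orepa import OREPABlock, orepa_compress, orepa_forward


@dataclass
class GELANConfig:
    c_in: int
    c_out: int
    n_units: int = 2

    def __post_init__(self) -> None:
        if self.c_in % 2 != 0:
            raise ValueError("c_in must be even (channel split)")

    @property
    def c_hidden(self) -> int:
        return self.c_in // 2


class OREPAGELAN:
    """GELAN split/partial-aggregation topology over OREPA convolution units."""

    def __init__(self, cfg: GELANConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.c_hidden
        self.cv1 = rng.normal(0, 1 / np.sqrt(cfg.c_in), (cfg.c_in, cfg.c_in))
        self.units = [OREPABlock.init(ch, ch, rng) for _ in range(cfg.n_units)]
        n_cat = (2 + cfg.n_units) * ch
        self.cv2 = rng.normal(0, 1 / np.sqrt(n_cat), (cfg.c_out, n_cat))

    def forward(self, x: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        if x.shape[0] != cfg.c_in:
            raise ValueError(f"expected {cfg.c_in} channels, got {x.shape[0]}")
        ch = cfg.c_hidden
        y = silu(conv1x1(x, self.cv1))
        parts = [y[:ch], y[ch:]]
        for unit in self.units:
            parts.append(silu(orepa_forward(parts[-1], unit)))
        return silu(conv1x1(np.concatenate(parts, axis=0), self.cv2))

    __call__ = forward

    @property
    def is_compressed(self) -> bool:
        return all(u.is_compressed for u in self.units)

    def compress(self) -> "OREPAGELAN":
        """Swap every OREPA unit to its compressed form (idempotent with warning)."""
        if self.is_compressed:
            warnings.warn("OREPAGELAN already compressed; compress() is a no-op",
                          stacklevel=2)
            return self
        self.units = [u if u.is_compressed else orepa_compress(u) for u in self.units]
        return self

    def n_parameters(self) -> int:
        return int(self.cv1.size + self.cv2.size + sum(u.n_parameters() for u in self.units))
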