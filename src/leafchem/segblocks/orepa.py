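"""Six-branch online reparameterized convolution (OREPA).

During training the block is a sum of six parallel *linear* branches — no
nonlinearity or normalization inside, each followed by a linear per-channel
scaling layer:

1. plain 3x3 convolution;
2. serial convolution: 1x1 expansion followed by a 3x3 convolution;
3. 1x1 serial convolution: two chained 1x1 convolutions;
4. average convolution: fixed 3x3 mean filter per channel, then learned 1x1
   channel mixing;
5. cosine convolution: fixed 3x3 cosine-basis (DCT) kernels with learned
   per-channel-pair mixing weights;
6. linear depthwise-separable convolution: depthwise 3x3, then pointwise 1x1.

Because every branch is a linear map with an effective receptive field of at
most 3x3, the whole block *folds exactly* into a single 3x3 convolution plus
bias (`orepa_compress`): serial branches by kernel composition, 1x1 kernels by
center embedding, fixed-filter branches by multiplying their fixed kernel into
the learned mixing weights.  Train-time and compressed forwards agree to
floating-point accumulation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from leafchem.segblocks.nn import conv1x1, conv2d, depthwise3x3

AVG_KERNEL = np.full((3, 3), 1.0 / 9.0)


def cosine_basis() -> np.ndarray:
    """Three fixed 3x3 DCT-II basis kernels (frequency pairs (0,1), (1,0), (1,1))."""
    def dct(u: int, v: int) -> np.ndarray:
        xs = np.arange(3)
        cu = np.cos(np.pi * (2 * xs + 1) * u / 6.0)
        cv = np.cos(np.pi * (2 * xs + 1) * v / 6.0)
        return np.outer(cu, cv)

    return np.stack([dct(0, 1), dct(1, 0), dct(1, 1)])


COS_BASIS = cosine_basis()

BRANCH_NAMES = ("conv3x3", "serial", "serial1x1", "average", "cosine", "depthwise_sep")


@dataclass
class OREPABlock:
    """Parameters of the six branches plus per-branch scaling and a shared bias.

    ``scales`` holds one per-output-channel scaling vector per branch (the
    linear scaling layer that replaces normalization).  After
    :func:`orepa_compress`, ``compressed_kernel``/``compressed_bias`` are
    populated and the branch parameters are no longer used.
    """

    c_in: int
    c_out: int
    w3: np.ndarray                 # (C_out, C_in, 3, 3)
    serial_1x1: np.ndarray         # (C_mid, C_in)
    serial_3x3: np.ndarray         # (C_out, C_mid, 3, 3)
    s1_first: np.ndarray           # (C_mid, C_in)
    s1_second: np.ndarray          # (C_out, C_mid)
    avg_mix: np.ndarray            # (C_out, C_in)
    cos_mix: np.ndarray            # (C_out, C_in, 3)
    dw_kernels: np.ndarray         # (C_in, 3, 3)
    pw_mix: np.ndarray             # (C_out, C_in)
    scales: dict[str, np.ndarray] = field(default_factory=dict)  # branch -> (C_out,)
    bias: np.ndarray = None        # type: ignore[assignment]
    compressed_kernel: np.ndarray | None = None
    compressed_bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bias is None:
            self.bias = np.zeros(self.c_out)
        for name in BRANCH_NAMES:
            self.scales.setdefault(name, np.ones(self.c_out))

    @property
    def is_compressed(self) -> bool:
        return self.compressed_kernel is not None

    @classmethod
    def init(cls, c_in: int, c_out: int, rng: np.random.Generator,
             c_mid: int | None = None) -> "OREPABlock":
        c_mid = c_mid or max(c_in, 2)
        s = 1.0 / np.sqrt(c_in * 9)
        return cls(
            c_in=c_in, c_out=c_out,
            w3=rng.normal(0, s, (c_out, c_in, 3, 3)),
            serial_1x1=rng.normal(0, 1 / np.sqrt(c_in), (c_mid, c_in)),
            serial_3x3=rng.normal(0, 1 / np.sqrt(c_mid * 9), (c_out, c_mid, 3, 3)),
            s1_first=rng.normal(0, 1 / np.sqrt(c_in), (c_mid, c_in)),
            s1_second=rng.normal(0, 1 / np.sqrt(c_mid), (c_out, c_mid)),
            avg_mix=rng.normal(0, 1 / np.sqrt(c_in), (c_out, c_in)),
            cos_mix=rng.normal(0, 1 / np.sqrt(3 * c_in), (c_out, c_in, 3)),
            dw_kernels=rng.normal(0, 1 / 3.0, (c_in, 3, 3)),
            pw_mix=rng.normal(0, 1 / np.sqrt(c_in), (c_out, c_in)),
            scales={name: rng.normal(1.0, 0.1, c_out) for name in BRANCH_NAMES},
            bias=rng.normal(0, 0.01, c_out),
        )

    @classmethod
    def zeros(cls, c_in: int, c_out: int, c_mid: int | None = None) -> "OREPABlock":
        c_mid = c_mid or max(c_in, 2)
        return cls(
            c_in=c_in, c_out=c_out,
            w3=np.zeros((c_out, c_in, 3, 3)),
            serial_1x1=np.zeros((c_mid, c_in)),
            serial_3x3=np.zeros((c_out, c_mid, 3, 3)),
            s1_first=np.zeros((c_mid, c_in)),
            s1_second=np.zeros((c_out, c_mid)),
            avg_mix=np.zeros((c_out, c_in)),
            cos_mix=np.zeros((c_out, c_in, 3)),
            dw_kernels=np.zeros((c_in, 3, 3)),
            pw_mix=np.zeros((c_out, c_in)),
            bias=np.zeros(c_out),
        )

    def n_parameters(self, compressed: bool | None = None) -> int:
        if compressed is None:
            compressed = self.is_compressed
        if compressed:
            return self.compressed_kernel.size + self.compressed_bias.size
        arrays = [self.w3, self.serial_1x1, self.serial_3x3, self.s1_first,
                  self.s1_second, self.avg_mix, self.cos_mix, self.dw_kernels,
                  self.pw_mix, self.bias, *self.scales.values()]
        return int(sum(a.size for a in arrays))


def _embed_1x1(weight: np.ndarray) -> np.ndarray:
    """Embed a (C_out, C_in) pointwise kernel at the center of a 3x3 kernel."""
    k = np.zeros((*weight.shape, 3, 3))
    k[:, :, 1, 1] = weight
    return k


def _branch_kernels(block: OREPABlock) -> dict[str, np.ndarray]:
    """Each branch folded to an equivalent (C_out, C_in, 3, 3) kernel."""
    return {
        "conv3x3": block.w3,
        # 1x1 then 3x3: compose over the middle channels
        "serial": np.einsum("omkl,mi->oikl", block.serial_3x3, block.serial_1x1),
        "serial1x1": _embed_1x1(block.s1_second @ block.s1_first),
        "average": np.einsum("oi,kl->oikl", block.avg_mix, AVG_KERNEL),
        "cosine": np.einsum("oib,bkl->oikl", block.cos_mix, COS_BASIS),
        "depthwise_sep": np.einsum("oi,ikl->oikl", block.pw_mix, block.dw_kernels),
    }


def branch_outputs(block: OREPABlock, x: np.ndarray) -> dict[str, np.ndarray]:
    """Train-time forward of each branch, computed as the actual sequential ops."""
    outs = {
        "conv3x3": conv2d(x, block.w3),
        "serial": conv2d(conv1x1(x, block.serial_1x1), block.serial_3x3),
        "serial1x1": conv1x1(conv1x1(x, block.s1_first), block.s1_second),
        "average": conv1x1(
            depthwise3x3(x, np.broadcast_to(AVG_KERNEL, (block.c_in, 3, 3))),
            block.avg_mix,
        ),
        "cosine": np.einsum(
            "oib,bihw->ohw", block.cos_mix,
            np.stack([depthwise3x3(x, np.broadcast_to(COS_BASIS[b], (block.c_in, 3, 3)))
                      for b in range(3)]),
            optimize=True,
        ),
        "depthwise_sep": conv1x1(depthwise3x3(x, block.dw_kernels), block.pw_mix),
    }
    return outs


def orepa_forward_train(x: np.ndarray, block: OREPABlock) -> np.ndarray:
    """Sum of the six scaled branch outputs plus bias — a pure linear map of x."""
    if block.is_compressed:
        raise ValueError("block already compressed; use orepa_forward")
    out = np.zeros((block.c_out, *x.shape[1:]))
    for name, branch_out in branch_outputs(block, x).items():
        out += block.scales[name][:, None, None] * branch_out
    return out + block.bias[:, None, None]


def orepa_fold_kernel(block: OREPABlock) -> np.ndarray:
    """The single 3x3 kernel equivalent to the six scaled branches."""
    kernel = np.zeros((block.c_out, block.c_in, 3, 3))
    for name, k in _branch_kernels(block).items():
        kernel += block.scales[name][:, None, None, None] * k
    return kernel


def orepa_compress(block: OREPABlock) -> OREPABlock:
    """Fold the six linearized branches into one 3x3 convolution + bias.

    Smaller kernels are zero-padded into the 3x3 (pointwise kernels embed at
    the center), serial branches merge by kernel composition, and the fixed
    average/cosine filters multiply into their learned mixing weights.
    """
    if block.is_compressed:
        raise ValueError("block already compressed")
    return replace(block, compressed_kernel=orepa_fold_kernel(block),
                   compressed_bias=block.bias.copy())


def orepa_forward(x: np.ndarray, block: OREPABlock) -> np.ndarray:
    """Inference forward: compressed single-conv path if available."""
    if block.is_compressed:
        return conv2d(x, block.compressed_kernel, block.compressed_bias)
    return orepa_forward_train(x, block)


# ---------------------------------------------------------------------------
# training support: analytic parameter gradients through the fold
# ---------------------------------------------------------------------------

def _kernel_grad(x: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Gradient of sum(delta * conv2d(x, K)) with respect to the 3x3 kernel K."""
    c_in, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, (h, w), axis=(1, 2))  # (C_in, 3, 3, H, W)
    return np.einsum("ohw,iklhw->oikl", delta, win, optimize=True)


def orepa_param_grad(block: OREPABlock, x: np.ndarray, delta: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of ``sum(delta * forward_train(x))`` for every parameter tensor.

    Uses the exact fold: the block's output is ``conv2d(x, K(theta)) + bias``
    with ``K`` (multi)linear in the parameters, so the chain rule runs through
    the folded-kernel gradient.
    """
    g_k = _kernel_grad(x, delta)  # (C_out, C_in, 3, 3)
    kernels = _branch_kernels(block)
    grads: dict[str, np.ndarray] = {
        "bias": delta.sum(axis=(1, 2)),
    }
    for name in BRANCH_NAMES:
        grads[f"scale.{name}"] = np.einsum("oikl,oikl->o", g_k, kernels[name])
    sc = {n: block.scales[n][:, None, None, None] for n in BRANCH_NAMES}
    grads["w3"] = sc["conv3x3"] * g_k
    g_serial = sc["serial"] * g_k
    grads["serial_3x3"] = np.einsum("oikl,mi->omkl", g_serial, block.serial_1x1)
    grads["serial_1x1"] = np.einsum("oikl,omkl->mi", g_serial, block.serial_3x3)
    g_s1 = (block.scales["serial1x1"][:, None] * g_k[:, :, 1, 1])  # (C_out, C_in)
    grads["s1_second"] = g_s1 @ block.s1_first.T
    grads["s1_first"] = block.s1_second.T @ g_s1
    grads["avg_mix"] = sc["average"][..., 0, 0] * np.einsum("oikl,kl->oi", g_k, AVG_KERNEL)
    grads["cos_mix"] = sc["cosine"][..., 0] * np.einsum("oikl,bkl->oib", g_k, COS_BASIS)
    g_dws = sc["depthwise_sep"] * g_k
    grads["pw_mix"] = np.einsum("oikl,ikl->oi", g_dws, block.dw_kernels)
    grads["dw_kernels"] = np.einsum("oikl,oi->ikl", g_dws, block.pw_mix)
    return grads


PARAM_FIELDS = ("w3", "serial_1x1", "serial_3x3", "s1_first", "s1_second",
                "avg_mix", "cos_mix", "dw_kernels", "pw_mix", "bias")


def fit_orepa(block: OREPABlock, inputs: list[np.ndarray], targets: list[np.ndarray],
              lr: float = 0.05, epochs: int = 30) -> list[float]:
    """Gradient-descent fit of the block to target maps; returns the loss curve.

    A small training harness for smoke tests and demos: mean-squared-error
    loss, plain gradient descent over all branch parameters and scales.
    """
    losses = []
    for _ in range(epochs):
        total = 0.0
        grads_acc: dict[str, np.ndarray] = {}
        for x, y in zip(inputs, targets):
            pred = orepa_forward_train(x, block)
            resid = pred - y
            total += float(np.mean(resid ** 2))
            delta = 2.0 * resid / resid.size
            for key, g in orepa_param_grad(block, x, delta).items():
                grads_acc[key] = grads_acc.get(key, 0.0) + g
        losses.append(total / len(inputs))
        for key, g in grads_acc.items():
            g = g / len(inputs)
            if key.startswith("scale."):
                block.scales[key.split(".", 1)[1]] -= lr * g
            else:
                setattr(block, key, getattr(block, key) - lr * g)
    return losses
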