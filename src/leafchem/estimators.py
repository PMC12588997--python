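"""Regression networks mapping a feature vector to a chemistry value.

Four architectures, trained one target at a time (separate nitrogen and
nicotine models):

* **MLP** — compact dense net (two hidden layers, 128/64 units, ReLU);
* **FCNN** — deeper/wider dense variant (256/128/64);
* **RNN** — tanh recurrent net over a chunked view of the feature vector;
* **LSTM** — gated recurrent net over the same sequence layout.

The recurrent models consume the flat feature vector through
:class:`SequenceLayout`: band-major chunks of length 80, i.e. one step per
spectral band carrying that band's mean and its 79 texture features (generic
vectors are zero-padded to a multiple of the chunk length).

Training is full NumPy: Adam, mean-squared-error loss on z-scored features
and target (statistics from the training rows only), seeded minibatch
shuffling, early stopping on validation loss with best-weight restoration.
Evaluation reports R^2 = 1 - SS_res/SS_tot and RMSE on the original target
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from leafchem.msio import BAND_ORDER

ARCHITECTURES = ("MLP", "FCNN", "RNN", "LSTM")


@dataclass
class ModelSpec:
    architecture: str = "MLP"
    hidden_sizes: tuple[int, ...] | None = None   # dense nets
    recurrent_hidden: int = 64                    # RNN/LSTM
    chunk_length: int = 80
    epochs: int = 400
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0
    patience: int = 60

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.hidden_sizes is None:
            self.hidden_sizes = (256, 128, 64) if self.architecture == "FCNN" else (128, 64)


@dataclass
class EvalReport:
    r2: float
    rmse: float
    n: int
    predictions: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


class SequenceLayout:
    """Deterministic, invertible reshaping of a flat feature vector to (T, d).

    With canonical 480-feature names the layout is band-major: step ``b`` is
    ``[band b mean, band b texture features...]`` (chunk length 80, 6 steps).
    Without names, the vector is zero-padded to a multiple of ``chunk_length``
    and reshaped row-major.
    """

    def __init__(self, n_features: int, chunk_length: int = 80,
                 names: list[str] | None = None):
        self.chunk_length = chunk_length
        self.n_features = n_features
        if names is not None and len(names) != n_features:
            raise ValueError("names length must match n_features")
        self.perm = self._band_major_perm(names) if names is not None else None
        if self.perm is not None and len(self.perm) % chunk_length != 0:
            self.perm = None  # fall back to the padded generic layout
        if self.perm is None:
            self.n_steps = -(-n_features // chunk_length)
            self.padded = self.n_steps * chunk_length
        else:
            self.n_steps = len(self.perm) // chunk_length
            self.padded = len(self.perm)

    @staticmethod
    def _band_major_perm(names: list[str]) -> np.ndarray | None:
        idx = {n: i for i, n in enumerate(names)}
        perm: list[int] = []
        for band in BAND_ORDER:
            mean_name = f"band_mean.{band}"
            if mean_name not in idx:
                return None
            perm.append(idx[mean_name])
            perm.extend(i for n, i in idx.items()
                        if n.startswith(f"{band}.") )
        if len(perm) != len(names):
            return None
        return np.asarray(perm)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(n, n_features) -> (n, T, chunk_length)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.perm is not None:
            out = x[:, self.perm]
        else:
            out = np.zeros((len(x), self.padded))
            out[:, : self.n_features] = x
        return out.reshape(len(x), self.n_steps, self.chunk_length)

    def inverse(self, seq: np.ndarray) -> np.ndarray:
        flat = np.asarray(seq).reshape(len(seq), self.padded)
        if self.perm is not None:
            out = np.empty_like(flat)
            out[:, self.perm] = flat
            return out
        return flat[:, : self.n_features]


def feature_to_sequence(x: np.ndarray, chunk_length: int = 80,
                        names: list[str] | None = None) -> np.ndarray:
    """Functional wrapper around :class:`SequenceLayout` (single vector or batch)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    layout = SequenceLayout(x.shape[1], chunk_length, names)
    return layout.forward(x)


# ---------------------------------------------------------------------------
# parameter containers + forward/backward
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


class _DenseNet:
    def __init__(self, d_in: int, hidden: tuple[int, ...], rng: np.random.Generator):
        sizes = [d_in, *hidden, 1]
        self.params = {}
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / a), (a, b))
            self.params[f"b{i}"] = np.zeros(b)
        self.n_layers = len(sizes) - 1

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        h = x
        acts = [h]
        for i in range(self.n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = z if i == self.n_layers - 1 else _relu(z)
            acts.append(h)
        if cache is not None:
            cache["acts"] = acts
        return h[:, 0]

    def backward(self, cache: dict, dout: np.ndarray) -> dict:
        acts = cache["acts"]
        grads = {}
        delta = dout[:, None]
        for i in range(self.n_layers - 1, -1, -1):
            h_prev = acts[i]
            grads[f"W{i}"] = h_prev.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.params[f"W{i}"].T) * (acts[i] > 0)
        return grads


class _RNNNet:
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_in)
        sh = 1.0 / np.sqrt(hidden)
        self.h = hidden
        self.params = {
            "Wx": rng.normal(0, s, (d_in, hidden)),
            "Wh": rng.normal(0, sh, (hidden, hidden)),
            "bh": np.zeros(hidden),
            "Wy": rng.normal(0, sh, (hidden, 1)),
            "by": np.zeros(1),
        }

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        n, T, d = x.shape
        h = np.zeros((n, self.h))
        hs = [h]
        for t in range(T):
            h = np.tanh(x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["bh"])
            hs.append(h)
        if cache is not None:
            cache["x"], cache["hs"] = x, hs
        return (h @ self.params["Wy"] + self.params["by"])[:, 0]

    def backward(self, cache: dict, dout: np.ndarray) -> dict:
        x, hs = cache["x"], cache["hs"]
        n, T, _ = x.shape
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wy"] = hs[-1].T @ dout[:, None]
        grads["by"] = np.array([dout.sum()])
        dh = dout[:, None] @ p["Wy"].T
        for t in range(T - 1, -1, -1):
            dz = dh * (1.0 - hs[t + 1] ** 2)
            grads["Wx"] += x[:, t].T @ dz
            grads["Wh"] += hs[t].T @ dz
            grads["bh"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
        return grads


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _LSTMNet:
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_in + hidden)
        self.h = hidden
        self.params = {
            "W": rng.normal(0, s, (d_in + hidden, 4 * hidden)),  # i, f, o, g
            "b": np.zeros(4 * hidden),
            "Wy": rng.normal(0, 1.0 / np.sqrt(hidden), (hidden, 1)),
            "by": np.zeros(1),
        }
        self.params["b"][hidden: 2 * hidden] = 1.0  # forget-gate bias

    def _gates(self, z):
        h = self.h
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h: 2 * h])
        o = _sigmoid(z[:, 2 * h: 3 * h])
        g = np.tanh(z[:, 3 * h:])
        return i, f, o, g

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        n, T, d = x.shape
        h = np.zeros((n, self.h))
        c = np.zeros((n, self.h))
        steps = []
        for t in range(T):
            zin = np.concatenate([x[:, t], h], axis=1)
            z = zin @ self.params["W"] + self.params["b"]
            i, f, o, g = self._gates(z)
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            steps.append((zin, i, f, o, g, c_prev, c, tc))
        if cache is not None:
            cache["steps"] = steps
        return (h @ self.params["Wy"] + self.params["by"])[:, 0]

    def backward(self, cache: dict, dout: np.ndarray) -> dict:
        steps = cache["steps"]
        p = self.params
        h = self.h
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        hT = steps[-1][3] * steps[-1][7]  # o * tanh(c)
        grads["Wy"] = hT.T @ dout[:, None]
        grads["by"] = np.array([dout.sum()])
        dh = dout[:, None] @ p["Wy"].T
        dc = np.zeros_like(dh)
        for t in range(len(steps) - 1, -1, -1):
            zin, i, f, o, g, c_prev, c, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g ** 2),
            ], axis=1)
            grads["W"] += zin.T @ dz
            grads["b"] += dz.sum(axis=0)
            dzin = dz @ p["W"].T
            dh = dzin[:, -h:]
            dc = dc * f
        return grads


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: object
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    layout: SequenceLayout | None
    history: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def predict(self, X) -> np.ndarray:
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        xv = X.to_numpy(dtype=float) if names else np.atleast_2d(np.asarray(X, dtype=float))
        z = (xv - self.x_mean) / self.x_std
        if self.layout is not None:
            z = self.layout.forward(z)
        raw = self.net.forward(z)
        return raw * self.y_std + self.y_mean


def _clip_grads(grads: dict, max_norm: float = 5.0) -> dict:
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        grads = {k: g * (max_norm / total) for k, g in grads.items()}
    return grads


def train(spec: ModelSpec, X_train, y_train, X_val, y_val,
          feature_names: list[str] | None = None) -> TrainedModel:
    """Train one network on (features, target) with early stopping.

    Standardization statistics come from the training rows only; validation
    rows steer early stopping and are never used for gradients.
    """
    if isinstance(X_train, pd.DataFrame):
        feature_names = feature_names or list(X_train.columns)
        X_train = X_train.to_numpy(dtype=float)
    if isinstance(X_val, pd.DataFrame):
        X_val = X_val.to_numpy(dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(spec.seed)

    x_mean = X_train.mean(axis=0)
    x_std = X_train.std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean, y_std = float(y_train.mean()), float(y_train.std() or 1.0)
    zt = (X_train - x_mean) / x_std
    zv = (X_val - x_mean) / x_std
    yt = (y_train - y_mean) / y_std
    yv = (y_val - y_mean) / y_std

    layout = None
    if spec.architecture in ("RNN", "LSTM"):
        layout = SequenceLayout(zt.shape[1], spec.chunk_length, feature_names)
        zt_in, zv_in = layout.forward(zt), layout.forward(zv)
        d_in = spec.chunk_length
        net = (_RNNNet if spec.architecture == "RNN" else _LSTMNet)(
            d_in, spec.recurrent_hidden, rng)
    else:
        zt_in, zv_in = zt, zv
        net = _DenseNet(zt.shape[1], tuple(spec.hidden_sizes), rng)

    opt = _Adam(net.params, spec.learning_rate)
    n = len(zt_in)
    best_val, best_params, since_best = np.inf, None, 0
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start: start + spec.batch_size]
            xb, yb = zt_in[idx], yt[idx]
            cache: dict = {}
            pred = net.forward(xb, cache)
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch}; reduce the learning rate"
                )
            ep_loss += loss * len(idx)
            grads = _clip_grads(net.backward(cache, 2.0 * resid / len(idx)))
            opt.step(net.params, grads)
        val_loss = float(np.mean((net.forward(zv_in) - yv) ** 2))
        history.append({"epoch": epoch, "train_loss": ep_loss / n, "val_loss": val_loss})
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    if best_params is not None:
        net.params.update(best_params)
    return TrainedModel(spec, net, x_mean, x_std, y_mean, y_std, layout,
                        history=pd.DataFrame(history))


def evaluate(model: TrainedModel, X_test, y_test, ids=None) -> EvalReport:
    """Held-out R^2 and RMSE; raises if the test target is constant."""
    y_test = np.asarray(y_test, dtype=float)
    if np.ptp(y_test) == 0:
        raise ValueError("test target is constant; R^2 undefined")
    pred = model.predict(X_test)
    ss_res = float(np.sum((y_test - pred) ** 2))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    detail = pd.DataFrame({"y_true": y_test, "y_pred": pred})
    if ids is not None:
        detail.insert(0, "leaf_id", list(ids))
    return EvalReport(r2=1.0 - ss_res / ss_tot,
                      rmse=float(np.sqrt(np.mean((y_test - pred) ** 2))),
                      n=len(y_test), predictions=detail)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str) -> None:
    """Write weights (npz), scaler, spec (YAML) and training log (CSV)."""
    import os

    import yaml

    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "weights.npz"), **model.net.params)
    scaler = {"x_mean": model.x_mean, "x_std": model.x_std,
              "y_mean": np.array(model.y_mean), "y_std": np.array(model.y_std)}
    if model.layout is not None and model.layout.perm is not None:
        scaler["layout_perm"] = model.layout.perm
    np.savez(os.path.join(directory, "scaler.npz"), **scaler)
    spec = model.spec
    with open(os.path.join(directory, "spec.yaml"), "w") as fh:
        yaml.safe_dump({
            "architecture": spec.architecture, "hidden_sizes": list(spec.hidden_sizes),
            "recurrent_hidden": spec.recurrent_hidden, "chunk_length": spec.chunk_length,
            "epochs": spec.epochs, "batch_size": spec.batch_size,
            "learning_rate": spec.learning_rate, "seed": spec.seed,
            "patience": spec.patience, "n_features": int(len(model.x_mean)),
        }, fh)
    if model.history is not None:
        model.history.to_csv(os.path.join(directory, "training_log.csv"), index=False)


def load_model(directory: str) -> TrainedModel:
    import os

    import yaml

    with open(os.path.join(directory, "spec.yaml")) as fh:
        meta = yaml.safe_load(fh)
    n_features = meta.pop("n_features")
    meta["hidden_sizes"] = tuple(meta["hidden_sizes"])
    spec = ModelSpec(**meta)
    scaler = dict(np.load(os.path.join(directory, "scaler.npz")))
    rng = np.random.default_rng(spec.seed)
    layout = None
    if spec.architecture in ("RNN", "LSTM"):
        layout = SequenceLayout(n_features, spec.chunk_length)
        if "layout_perm" in scaler:
            perm = scaler["layout_perm"].astype(int)
            layout.perm = perm
            layout.n_steps = len(perm) // spec.chunk_length
            layout.padded = len(perm)
        net = (_RNNNet if spec.architecture == "RNN" else _LSTMNet)(
            spec.chunk_length, spec.recurrent_hidden, rng)
    else:
        net = _DenseNet(n_features, tuple(spec.hidden_sizes), rng)
    weights = dict(np.load(os.path.join(directory, "weights.npz")))
    net.params.update(weights)
    return TrainedModel(spec, net, scaler["x_mean"], scaler["x_std"],
                        float(scaler["y_mean"]), float(scaler["y_std"]), layout)
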