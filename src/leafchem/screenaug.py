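"""Feature screening, training-set augmentation, and the 7:2:1 split.

Screening methods: Pearson |r| threshold, variance threshold, LASSO and
Elastic Net (coordinate descent via scikit-learn on z-scored features).
Augmentation perturbs feature vectors only — additive Gaussian noise
(variance 0.01), a random multiplicative scale and a random offset in
(-0.01, 0.01) — and is only ever applied to the training partition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Lasso, LassoCV, LinearRegression, Ridge

#: coefficients below this magnitude are coordinate-descent float dust, not
#: genuine selections
COEF_ZERO_TOL = 1e-10


@dataclass
class ScreeningResult:
    method: str
    params: dict
    selected_names: list[str]
    scores: pd.Series = field(repr=False)
    converged: bool = True

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps({
            "method": self.method, "params": self.params,
            "selected_names": list(self.selected_names),
            "scores": {k: float(v) for k, v in self.scores.items()},
            "converged": self.converged,
        }, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X), columns=[f"f{i}" for i in range(np.asarray(X).shape[1])])


def pearson_screen(X, y, threshold: float) -> ScreeningResult:
    """Keep features with |Pearson r| strictly greater than the threshold.

    Zero-variance features get r := 0 (and are therefore dropped for any
    positive threshold).
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("Pearson screening needs at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; correlation undefined")
    xv = X.to_numpy(dtype=float)
    xc = xv - xv.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, xc.T @ yc / (sx * sy + (sx == 0)), 0.0)
    scores = pd.Series(np.abs(r), index=X.columns)
    selected = scores.index[scores > threshold].tolist()
    return ScreeningResult("pearson", {"threshold": threshold}, selected, scores)


def variance_screen(X, threshold: float) -> ScreeningResult:
    """Keep features whose sample variance exceeds the threshold (raw values)."""
    X = _as_frame(X)
    if len(X) < 2:
        raise ValueError("variance screening needs at least 2 samples")
    scores = pd.Series(X.to_numpy(dtype=float).var(axis=0, ddof=1), index=X.columns)
    selected = scores.index[scores > threshold].tolist()
    return ScreeningResult("variance", {"threshold": threshold}, selected, scores)


def _zscore(xv: np.ndarray) -> np.ndarray:
    mu = xv.mean(axis=0)
    sd = xv.std(axis=0)
    sd[sd == 0] = 1.0
    return (xv - mu) / sd


def lasso_screen(X, y, strength: float | None = None, seed: int = 0,
                 max_iter: int = 20000) -> ScreeningResult:
    """L1-penalized linear selection: features with nonzero coefficients.

    ``strength`` is the penalty weight; ``None`` picks it by internal
    cross-validation, ``0`` degenerates to ordinary least squares (all
    coefficients generically nonzero).  Non-convergence within the iteration
    budget is flagged on the result rather than raised.
    """
    X = _as_frame(X)
    xv = _zscore(X.to_numpy(dtype=float))
    y = np.asarray(y, dtype=float)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if strength == 0:
            model = LinearRegression().fit(xv, y)
            alpha = 0.0
        elif strength is None:
            model = LassoCV(cv=5, random_state=seed, max_iter=max_iter).fit(xv, y)
            alpha = float(model.alpha_)
        else:
            model = Lasso(alpha=strength, max_iter=max_iter, random_state=seed).fit(xv, y)
            alpha = strength
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn("LASSO did not converge within the iteration budget; "
                          "selection flagged as partial", stacklevel=2)
    scores = pd.Series(np.abs(np.ravel(model.coef_)), index=X.columns)
    selected = scores.index[scores > COEF_ZERO_TOL].tolist()
    return ScreeningResult("lasso", {"strength": alpha, "seed": seed}, selected,
                           scores, converged=converged)


def elasticnet_screen(X, y, l1_strength: float | None = None,
                      l2_strength: float | None = None, seed: int = 0,
                      max_iter: int = 20000) -> ScreeningResult:
    """Mixed L1+L2 selection (grouping effect on correlated features).

    The penalty is ``l1*||w||_1 + l2*||w||_2^2``; ``l1=0`` is the ridge limit
    (no selection pressure, all coefficients nonzero), ``l2=0`` reduces to
    :func:`lasso_screen`.
    """
    X = _as_frame(X)
    if l1_strength is None or l2_strength is None:
        l1_strength = 0.01 if l1_strength is None else l1_strength
        l2_strength = 0.01 if l2_strength is None else l2_strength
    xv = _zscore(X.to_numpy(dtype=float))
    y = np.asarray(y, dtype=float)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if l1_strength == 0:
            model = Ridge(alpha=2.0 * l2_strength * len(y)).fit(xv, y)
        else:
            # sklearn parameterization: alpha*l1_ratio = l1, 0.5*alpha*(1-l1_ratio) = l2
            alpha = l1_strength + 2.0 * l2_strength
            model = ElasticNet(alpha=alpha, l1_ratio=l1_strength / alpha,
                               max_iter=max_iter, random_state=seed).fit(xv, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn("Elastic Net did not converge within the iteration budget",
                          stacklevel=2)
    scores = pd.Series(np.abs(np.ravel(model.coef_)), index=X.columns)
    selected = scores.index[scores > COEF_ZERO_TOL].tolist()
    return ScreeningResult("elasticnet", {"l1": l1_strength, "l2": l2_strength, "seed": seed},
                           selected, scores, converged=converged)


@dataclass
class AugmentConfig:
    """Feature-space augmentation parameters (training partition only)."""

    gaussian_mean: float = 0.0
    gaussian_variance: float = 0.01
    scale_range: tuple[float, float] = (0.9, 1.1)
    offset_range: tuple[float, float] = (-0.01, 0.01)
    seed: int = 0


def augment(rows, cfg: AugmentConfig, n_copies: int = 1, partition: str = "train"):
    """Return original rows plus ``n_copies`` perturbed copies of each.

    Each copy is ``(x + eps) * s + o`` with elementwise Gaussian ``eps``, one
    uniform scale ``s`` and one uniform offset ``o`` per row.  Targets are
    never part of ``rows``; augmenting any partition other than the training
    set raises.
    """
    if partition != "train":
        raise ValueError(f"augmentation is restricted to the training set, got {partition!r}")
    frame = isinstance(rows, pd.DataFrame)
    x = rows.to_numpy(dtype=float) if frame else np.asarray(rows, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    copies = [x]
    for _ in range(n_copies):
        eps = rng.normal(cfg.gaussian_mean, np.sqrt(cfg.gaussian_variance), size=x.shape)
        s = rng.uniform(*cfg.scale_range, size=(len(x), 1))
        o = rng.uniform(*cfg.offset_range, size=(len(x), 1))
        copies.append((x + eps) * s + o)
    out = np.vstack(copies)
    if frame:
        return pd.DataFrame(out, columns=rows.columns)
    return out


@dataclass
class DatasetSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(i), part) for part, idx in
                (("train", self.train), ("val", self.val), ("test", self.test))
                for i in idx]
        return pd.DataFrame(rows, columns=["index", "partition"]).sort_values("index")


def split_7_2_1(n_or_records, seed: int = 0, group_by=None) -> DatasetSplit:
    """Shuffled 7:2:1 partition: floor(0.7n) / floor(0.2n) / remainder.

    ``group_by`` (a per-record label array) keeps all records of one group —
    e.g. all leaves of one plant — in a single partition; a warning is issued
    if the group structure cannot match the target sizes within one group.
    """
    n = n_or_records if isinstance(n_or_records, int) else len(n_or_records)
    if n < 10:
        raise ValueError("7:2:1 split needs at least 10 records")
    n_train, n_val = int(np.floor(0.7 * n)), int(np.floor(0.2 * n))
    rng = np.random.default_rng(seed)
    if group_by is None:
        perm = rng.permutation(n)
        return DatasetSplit(np.sort(perm[:n_train]),
                            np.sort(perm[n_train:n_train + n_val]),
                            np.sort(perm[n_train + n_val:]))
    group_by = np.asarray(group_by)
    groups = list(pd.unique(group_by))
    rng.shuffle(groups)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    targets = {"train": n_train, "val": n_val, "test": n - n_train - n_val}
    max_group = 0
    for g in groups:
        idx = np.flatnonzero(group_by == g)
        max_group = max(max_group, len(idx))
        deficit = {p: targets[p] - len(parts[p]) for p in parts}
        best = max(deficit, key=lambda p: deficit[p])
        parts[best].extend(idx.tolist())
    for p in parts:
        if abs(len(parts[p]) - targets[p]) > max_group:
            warnings.warn(
                f"grouped split misses the 7:2:1 target for {p!r} by more than one group",
                stacklevel=2,
            )
    return DatasetSplit(*(np.sort(np.array(parts[p], dtype=int))
                          for p in ("train", "val", "test")))
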