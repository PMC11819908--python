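"""Four-family IC regression harness with 10-fold cross-validation.

Families: ordinary least squares, random forest, gradient boosting, and a
dense neural network with batch normalization. Tree families expose the
tree-count grid {10, 50, 100, 200, 300, 500}; NN widths default to the
per-domain architectures in :data:`DOMAIN_NN_WIDTHS`.

Evaluation reports MSE, MAE, R² and median absolute error on both the
held-out fold and the training portion of every split, plus their
across-fold averages.

The gradient-boosting family is backed by scikit-learn's
``GradientBoostingRegressor``; the dense NN is the in-package NumPy
implementation (see :mod:`icpredict.nn`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .nn import DenseRegressor

__all__ = [
    "FAMILIES",
    "TREE_COUNT_GRID",
    "DOMAIN_NN_WIDTHS",
    "ModelSpec",
    "CVReport",
    "SpecError",
    "metrics",
    "make_model",
    "train",
    "predict_ic",
    "kfold_cv",
    "compare_models",
]

FAMILIES = ("linear", "random_forest", "gradient_boosting", "dense_nn")
TREE_COUNT_GRID = (10, 50, 100, 200, 300, 500)

#: Per-domain hidden-layer widths of the dense NN architectures.
DOMAIN_NN_WIDTHS = {
    "locomotion": (32, 32, 32, 32),
    "sensory": (16, 16, 16, 16),
    "psychology": (16, 16, 16, 16),
    "cognition": (16, 32, 16),
    "vitality": (8, 16, 16, 8),
}

METRIC_NAMES = ("mse", "mae", "r2", "medae")


class SpecError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One regressor family with its hyperparameters."""

    family: str
    tree_count: Optional[int] = None
    layer_widths: Optional[tuple] = None
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family in ("random_forest", "gradient_boosting"):
            count = self.tree_count if self.tree_count is not None else 100
            if count not in TREE_COUNT_GRID:
                raise SpecError(
                    f"tree_count {count} not in the grid {TREE_COUNT_GRID}")
            object.__setattr__(self, "tree_count", count)
        if self.family == "dense_nn":
            if not self.layer_widths:
                raise SpecError("dense_nn requires non-empty layer_widths")
            object.__setattr__(self, "layer_widths", tuple(self.layer_widths))

    @classmethod
    def for_domain(cls, family: str, domain: str, **kwargs) -> "ModelSpec":
        if family == "dense_nn" and "layer_widths" not in kwargs:
            kwargs["layer_widths"] = DOMAIN_NN_WIDTHS[domain]
        return cls(family=family, **kwargs)

    def label(self) -> str:
        if self.family in ("random_forest", "gradient_boosting"):
            return f"{self.family}(trees={self.tree_count})"
        if self.family == "dense_nn":
            return f"dense_nn{self.layer_widths}"
        return self.family


def metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> dict:
    """MSE, MAE, R² (about the mean of ``y_true``) and median absolute error.

    R² on a constant target is undefined and reported as NaN with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise InputError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise InputError("empty inputs")
    err = y_pred - y_true
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    medae = float(np.median(np.abs(err)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant y_true: R² undefined, reporting NaN", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return {"mse": mse, "mae": mae, "r2": r2, "medae": medae}


def make_model(spec: ModelSpec):
    """Instantiate an unfitted regressor for the spec."""
    if spec.family == "linear":
        return LinearRegression(**spec.hyperparams)
    if spec.family == "random_forest":
        return RandomForestRegressor(
            n_estimators=spec.tree_count, random_state=spec.seed,
            **spec.hyperparams)
    if spec.family == "gradient_boosting":
        return GradientBoostingRegressor(
            n_estimators=spec.tree_count, random_state=spec.seed,
            **spec.hyperparams)
    if spec.family == "dense_nn":
        return DenseRegressor(spec.layer_widths, seed=spec.seed, **spec.hyperparams)
    raise SpecError(f"unknown family {spec.family!r}")


def train(model, X, y):
    """Fit ``model`` in place and return it."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise InputError("X must be 2-D with one row per label")
    if len(y) == 0:
        raise InputError("empty training set")
    model.fit(X, y)
    return model


def predict_ic(model, X) -> np.ndarray:
    """Predict IC scores, clipping raw regression output to [0, 1]."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    try:
        raw = model.predict(X)
    except Exception as exc:  # sklearn raises NotFittedError, ours RuntimeError
        raise RuntimeError(f"model not ready for prediction: {exc}") from exc
    clipped = np.clip(np.asarray(raw, dtype=float), 0.0, 1.0)
    return float(clipped[0]) if single else clipped


@dataclass
class CVReport:
    """Per-fold and fold-averaged metrics on test and train partitions."""

    spec_label: str
    k: int
    seed: int
    fold_test: list
    fold_train: list
    test: dict = field(init=False)
    train: dict = field(init=False)

    def __post_init__(self) -> None:
        self.test = self._average(self.fold_test)
        self.train = self._average(self.fold_train)

    @staticmethod
    def _average(folds: list) -> dict:
        out = {}
        for name in METRIC_NAMES:
            values = np.array([f[name] for f in folds], dtype=float)
            finite = values[np.isfinite(values)]
            if len(finite) < len(values):
                warnings.warn(
                    f"{len(values) - len(finite)} fold(s) had undefined {name}; "
                    "excluded from the average", stacklevel=2)
            out[name] = float(finite.mean()) if len(finite) else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "spec": self.spec_label,
            "k": self.k,
            "seed": self.seed,
            "test": self.test,
            "train": self.train,
            "fold_test": self.fold_test,
            "fold_train": self.fold_train,
        }


def kfold_folds(n: int, k: int, seed: int) -> list:
    """Shuffle indices once with ``seed``, cut into k near-equal contiguous
    folds. Returns a list of (train_idx, test_idx) pairs covering every
    example exactly once as test."""
    if k < 2:
        raise InputError("k must be >= 2")
    if k > n:
        raise InputError(f"k={k} exceeds dataset size n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = []
    start = 0
    for size in sizes:
        test_idx = order[start:start + size]
        train_idx = np.concatenate([order[:start], order[start + size:]])
        folds.append((train_idx, test_idx))
        start += size
    return folds


def kfold_cv(spec: ModelSpec, X, y, k: int = 10, seed: int = 0) -> CVReport:
    """k-fold cross-validation of one spec; metrics on held-out and training
    portions of every split, averaged across folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fold_test, fold_train = [], []
    for train_idx, test_idx in kfold_folds(len(y), k, seed):
        model = train(make_model(spec), X[train_idx], y[train_idx])
        pred_test = predict_ic(model, X[test_idx])
        pred_train = predict_ic(model, X[train_idx])
        fold_test.append(metrics(y[test_idx], pred_test))
        fold_train.append(metrics(y[train_idx], pred_train))
    return CVReport(spec.label(), k, seed, fold_test, fold_train)


def compare_models(X, y, specs: Sequence[ModelSpec], k: int = 10, seed: int = 0) -> pd.DataFrame:
    """One row per spec with test/train metric blocks (cross-validated)."""
    rows = []
    for spec in specs:
        report = kfold_cv(spec, X, y, k=k, seed=seed)
        row = {"method": report.spec_label, "k": k, "seed": seed}
        for part in ("test", "train"):
            for name in METRIC_NAMES:
                row[f"{part}_{name}"] = getattr(report, part)[name]
        rows.append(row)
    columns = ["method", "k", "seed"] + [
        f"{part}_{name}" for part in ("test", "train") for name in METRIC_NAMES
    ]
    return pd.DataFrame(rows, columns=columns)
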