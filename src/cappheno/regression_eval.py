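"""Regression scoring: R2/RMSE/MSE/MAE, k-fold CV, standard scores.

The weight models are scored by the coefficient of determination
R2 = 1 - SS_res/SS_tot, the mean squared error, its square root, and the
mean absolute error, averaged over a seeded k-fold cross-validation in
which every sample is held out exactly once and fold sizes differ by at
most one.  Standard scores z = (extreme - mean)/sd summarise the trait
table extremes; they are reported at full precision alongside the
half-up 2-decimal rounding used in the published trait summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .reference import WEIGHT_COLUMN

__all__ = [
    "RegressionMetrics",
    "FoldPlan",
    "ConstantTargetError",
    "regression_metrics",
    "kfold_split",
    "cross_validate",
    "standard_score",
    "round_half_up",
    "minmax_normalize",
]


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    mse: float
    mae: float


class ConstantTargetError(ValueError):
    """R2 is undefined for a constant target; the remaining metrics are
    attached as ``.metrics`` (with r2 = nan)."""

    def __init__(self, message: str, metrics: RegressionMetrics):
        super().__init__(message)
        self.metrics = metrics


def regression_metrics(y: np.ndarray, y_hat: np.ndarray) -> RegressionMetrics:
    """R2, RMSE, MSE and MAE of a prediction set (m >= 2)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be equal-length 1-D arrays")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    mse = float(mean_squared_error(y, y_hat))
    mae = float(mean_absolute_error(y, y_hat))
    rmse = math.sqrt(mse)
    if np.ptp(y) == 0:
        raise ConstantTargetError(
            "R2 undefined for constant y",
            RegressionMetrics(r2=float("nan"), rmse=rmse, mse=mse, mae=mae),
        )
    r2 = float(r2_score(y, y_hat))
    return RegressionMetrics(r2=r2, rmse=rmse, mse=mse, mae=mae)


@dataclass
class FoldPlan:
    """Seeded k-fold assignment: each sample in exactly one fold, fold sizes
    differing by at most one."""

    n: int
    k: int
    assignment: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment != fold)[0]


def kfold_split(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Seeded shuffle followed by a contiguous partition into k folds."""
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n")
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return FoldPlan(n=n, k=k, assignment=assignment, seed=seed)


def cross_validate(
    model_factory,
    table: pd.DataFrame,
    plan: FoldPlan,
    features: list[str] | None = None,
    target: str = WEIGHT_COLUMN,
) -> RegressionMetrics:
    """Fit on k-1 folds, score the held-out fold, average the four metrics."""
    if len(table) != plan.n:
        raise ValueError("fold plan length does not match the table")
    features = features or [c for c in table.columns if c != target]
    X = table[features].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    per_fold = []
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        model = model_factory()
        model.fit(X[tr], y[tr])
        per_fold.append(regression_metrics(y[te], model.predict(X[te])))
    return RegressionMetrics(
        r2=float(np.mean([m.r2 for m in per_fold])),
        rmse=float(np.mean([m.rmse for m in per_fold])),
        mse=float(np.mean([m.mse for m in per_fold])),
        mae=float(np.mean([m.mae for m in per_fold])),
    )


def standard_score(extreme: float, mean: float, std: float) -> float:
    """z = (extreme - mean) / std; full precision (round separately)."""
    if std <= 0:
        raise ValueError("std must be positive")
    return (extreme - mean) / std


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention of the trait summary table."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def minmax_normalize(
    values: np.ndarray, lo: float | None = None, hi: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Min-max scale to [0, 1]; returns (scaled, lo, hi) for inversion."""
    values = np.asarray(values, dtype=float)
    lo = float(values.min()) if lo is None else lo
    hi = float(values.max()) if hi is None else hi
    if hi == lo:
        return np.zeros_like(values), lo, hi
    return (values - lo) / (hi - lo), lo, hi
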