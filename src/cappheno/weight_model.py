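"""Cap-weight prediction: correlation ranking, input groups, GWO-tuned SVR.

Weight is predicted from a small group of traits selected by their Pearson
correlation with measured weight.  The fixed nested groups M1-M4 follow the
published design (M1 = {Area, Perimeter, External rectangular width, Long
axis} down to M4 = {Perimeter}); a data-driven mode instead nests the top
correlated traits of the table at hand.

The regressor is an RBF-kernel epsilon-SVR on min-max-normalised features
and target.  Its hyperparameters (C, gamma, epsilon) are tuned by the Grey
Wolf Optimizer: a population of candidate parameter vectors moves toward
the three current best ("alpha, beta, delta") under an exploration
coefficient decaying linearly from 2 to 0, minimising the cross-validated
RMSE.  The search runs in log10 parameter space.

The LSTM-family models (LSTM, BiLSTM, Optuna-tuned LSTM, WOA-BiLSTM with
attention) are registered plug-in slots only: their registry entries raise
until an external implementation is registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .phenotype import CapPhenotype
from .reference import (
    CORRELATION_EXCLUSION_CUT,
    INPUT_GROUPS,
    TRAIT_NAMES,
    WEIGHT_COLUMN,
)
from .regression_eval import (
    FoldPlan,
    RegressionMetrics,
    cross_validate,
    minmax_normalize,
    regression_metrics,
)

__all__ = [
    "CorrelationRanking",
    "InputGroup",
    "GWOConfig",
    "WeightModel",
    "OptimizationFailureError",
    "ModelUnavailableError",
    "MODEL_REGISTRY",
    "register_model",
    "pearson",
    "rank_and_group",
    "gwo_optimize",
    "fit_gwo_svm",
    "predict_weight",
]


class OptimizationFailureError(RuntimeError):
    """The optimizer never sampled a finite objective value."""


class ModelUnavailableError(NotImplementedError):
    """A registered plug-in slot without an implementation."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length (>= 3) vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationRanking:
    """Per-trait correlation with weight, in descending order."""

    values: dict[str, float]
    order: list[str]
    excluded: list[str]


@dataclass
class InputGroup:
    name: str
    features: tuple[str, ...]


def rank_and_group(
    table: pd.DataFrame, data_driven: bool = False
) -> tuple[CorrelationRanking, list[InputGroup]]:
    """Correlation ranking of the 11 traits against weight, plus the nested
    input groups (fixed M1-M4 by default; derived from the ranking when
    ``data_driven``)."""
    missing = [c for c in (*TRAIT_NAMES, WEIGHT_COLUMN) if c not in table.columns]
    if missing:
        raise KeyError(f"table is missing columns {missing}")
    w = table[WEIGHT_COLUMN].to_numpy(dtype=float)
    values = {name: pearson(table[name].to_numpy(dtype=float), w) for name in TRAIT_NAMES}
    order = sorted(values, key=lambda k: -abs(values[k]))
    excluded = [k for k in order if abs(values[k]) < CORRELATION_EXCLUSION_CUT]
    order = [k for k in order if k not in excluded]
    ranking = CorrelationRanking(values=values, order=order, excluded=excluded)

    if data_driven:
        top = ranking.order[:4]
        groups = [
            InputGroup(name=f"M{i}", features=tuple(top[: 4 - (i - 1)]))
            for i in range(1, 5)
        ]
    else:
        groups = [InputGroup(name=k, features=v) for k, v in INPUT_GROUPS.items()]
    return ranking, groups


# ---------------------------------------------------------------------------
# Grey Wolf Optimizer
# ---------------------------------------------------------------------------


def _default_bounds() -> dict[str, tuple[float, float]]:
    # log10 bounds: C in [1e-2, 1e3], gamma in [1e-4, 1e1], epsilon in [1e-3, 1]
    return {"log10_C": (-2.0, 3.0), "log10_gamma": (-4.0, 1.0), "log10_epsilon": (-3.0, 0.0)}


@dataclass
class GWOConfig:
    n_wolves: int = 20
    n_iters: int = 100
    bounds: dict[str, tuple[float, float]] = field(default_factory=_default_bounds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wolves < 1 or self.n_iters < 0:
            raise ValueError("need n_wolves >= 1 and n_iters >= 0")
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds[{k!r}] needs lo < hi")


def gwo_optimize(objective, cfg: GWOConfig) -> tuple[np.ndarray, float, list[float]]:
    """Minimise ``objective`` over the box in ``cfg.bounds``.

    Returns (best position, best score, best-so-far trace); the trace is
    monotone non-increasing and the whole run is reproducible per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.bounds)
    lo = np.array([cfg.bounds[k][0] for k in names])
    hi = np.array([cfg.bounds[k][1] for k in names])
    dim = len(names)

    X = rng.uniform(lo, hi, size=(cfg.n_wolves, dim))
    scores = np.array([objective(x) for x in X], dtype=float)
    order = np.argsort(scores)
    if not np.isfinite(scores[order[0]]):
        raise OptimizationFailureError("objective not finite at any sampled point")
    best_x = X[order[0]].copy()
    best_s = float(scores[order[0]])
    trace = [best_s]

    for t in range(cfg.n_iters):
        leaders = X[order[: min(3, cfg.n_wolves)]]
        while len(leaders) < 3:
            leaders = np.vstack([leaders, leaders[-1]])
        a = 2.0 - 2.0 * t / max(cfg.n_iters, 1)
        candidates = []
        for leader in leaders:
            A = 2.0 * a * rng.random((cfg.n_wolves, dim)) - a
            C = 2.0 * rng.random((cfg.n_wolves, dim))
            D = np.abs(C * leader - X)
            candidates.append(leader - A * D)
        X = np.clip(np.mean(candidates, axis=0), lo, hi)
        scores = np.array([objective(x) for x in X], dtype=float)
        order = np.argsort(scores)
        if np.isfinite(scores[order[0]]) and scores[order[0]] < best_s:
            best_s = float(scores[order[0]])
            best_x = X[order[0]].copy()
        trace.append(best_s)
    return best_x, best_s, trace


# ---------------------------------------------------------------------------
# GWO-tuned SVR
# ---------------------------------------------------------------------------


@dataclass
class WeightModel:
    """Fitted weight predictor: input group, min-max normalisation
    parameters, GWO-chosen SVR hyperparameters, and CV metrics (on the
    normalised scale; ``cv_rmse_grams`` restates RMSE in grams)."""

    group: InputGroup
    feature_lo: dict[str, float]
    feature_hi: dict[str, float]
    y_lo: float
    y_hi: float
    C: float
    gamma: float
    epsilon: float
    svr: SVR
    cv_metrics: RegressionMetrics
    cv_rmse_grams: float


class _NormalizedSVR:
    """SVR factory operating on already-normalised arrays (for CV)."""

    def __init__(self, C: float, gamma: float, epsilon: float):
        self.svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)

    def fit(self, X, y):
        self.svr.fit(X, y)
        return self

    def predict(self, X):
        return self.svr.predict(X)


def _normalized_frame(
    table: pd.DataFrame, features: tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float], float, float]:
    norm = {}
    lo_d: dict[str, float] = {}
    hi_d: dict[str, float] = {}
    for f in features:
        scaled, lo, hi = minmax_normalize(table[f].to_numpy(dtype=float))
        norm[f] = scaled
        lo_d[f], hi_d[f] = lo, hi
    y_scaled, y_lo, y_hi = minmax_normalize(table[WEIGHT_COLUMN].to_numpy(dtype=float))
    norm[WEIGHT_COLUMN] = y_scaled
    return pd.DataFrame(norm), lo_d, hi_d, y_lo, y_hi


def fit_gwo_svm(
    table: pd.DataFrame,
    group: InputGroup,
    plan: FoldPlan,
    cfg: GWOConfig | None = None,
) -> WeightModel:
    """Tune (C, gamma, epsilon) by GWO on mean CV RMSE, then refit on all data.

    Features and target are min-max normalised to [0, 1] before fitting;
    the stored parameters invert the target scaling at prediction time.
    """
    cfg = cfg or GWOConfig()
    missing = [f for f in group.features if f not in table.columns]
    if missing:
        raise KeyError(f"table is missing group features {missing}")
    norm, lo_d, hi_d, y_lo, y_hi = _normalized_frame(table, group.features)
    features = list(group.features)

    def objective(vec: np.ndarray) -> float:
        C, gamma, epsilon = (10.0**v for v in vec)
        try:
            m = cross_validate(
                lambda: _NormalizedSVR(C, gamma, epsilon), norm, plan, features=features
            )
        except Exception:
            return float("inf")
        return m.rmse

    best, _, _ = gwo_optimize(objective, cfg)
    C, gamma, epsilon = (float(10.0**v) for v in best)
    cv = cross_validate(lambda: _NormalizedSVR(C, gamma, epsilon), norm, plan, features=features)
    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
    svr.fit(norm[features].to_numpy(), norm[WEIGHT_COLUMN].to_numpy())
    return WeightModel(
        group=group,
        feature_lo=lo_d,
        feature_hi=hi_d,
        y_lo=y_lo,
        y_hi=y_hi,
        C=C,
        gamma=gamma,
        epsilon=epsilon,
        svr=svr,
        cv_metrics=cv,
        cv_rmse_grams=cv.rmse * (y_hi - y_lo),
    )


def _phenotype_features(phenotype) -> dict[str, float]:
    if isinstance(phenotype, CapPhenotype):
        return phenotype.to_row()
    if isinstance(phenotype, pd.Series):
        return phenotype.to_dict()
    return dict(phenotype)


def predict_weight(model: WeightModel, phenotype) -> float:
    """Predict cap weight (grams) from a phenotype record.

    Accepts a CapPhenotype, a mapping, or a pandas Series; features are
    bound by name, so supplying extras or reordering changes nothing.
    Values far outside the training range (more than one range-width beyond
    either end) trigger an out-of-domain warning.
    """
    row = _phenotype_features(phenotype)
    x = []
    for f in model.group.features:
        if f not in row or row[f] is None:
            raise KeyError(f"phenotype is missing model feature {f!r}")
        v = float(row[f])
        lo, hi = model.feature_lo[f], model.feature_hi[f]
        span = hi - lo
        if span > 0 and not (lo - span <= v <= hi + span):
            warnings.warn(
                f"feature {f!r}={v:.3g} is far outside the training range "
                f"[{lo:.3g}, {hi:.3g}]",
                stacklevel=2,
            )
        x.append((v - lo) / span if span > 0 else 0.0)
    y_norm = float(model.svr.predict(np.array([x]))[0])
    return model.y_lo + y_norm * (model.y_hi - model.y_lo)


def rbf_predict(
    support_vectors: np.ndarray,
    dual_coef: np.ndarray,
    intercept: float,
    gamma: float,
    X: np.ndarray,
) -> np.ndarray:
    """Evaluate an RBF-SVR decision function from its support data (used
    when reloading a JSON-serialised model)."""
    d2 = ((X[:, None, :] - support_vectors[None, :, :]) ** 2).sum(axis=2)
    return (np.exp(-gamma * d2) @ dual_coef.ravel()) + intercept


# ---------------------------------------------------------------------------
# Model registry (plug-in slots)
# ---------------------------------------------------------------------------

MODEL_REGISTRY: dict[str, object] = {}


def register_model(name: str):
    """Register a weight-model training callable under ``name``."""

    def deco(fn):
        MODEL_REGISTRY[name] = fn
        return fn

    return deco


def _unavailable(name: str):
    def stub(*args, **kwargs):
        raise ModelUnavailableError(
            f"{name} is a plug-in slot; register an implementation with "
            f"register_model({name!r})"
        )

    return stub


register_model("gwo_svm")(fit_gwo_svm)


@register_model("svr")
def fit_svr_default(
    table: pd.DataFrame, group: InputGroup, plan: FoldPlan, cfg=None
) -> WeightModel:
    """Plain SVR with sklearn defaults (no metaheuristic tuning)."""
    norm, lo_d, hi_d, y_lo, y_hi = _normalized_frame(table, group.features)
    features = list(group.features)
    C, gamma, epsilon = 1.0, "scale", 0.1
    cv = cross_validate(lambda: _NormalizedSVR(C, gamma, epsilon), norm, plan, features=features)
    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
    svr.fit(norm[features].to_numpy(), norm[WEIGHT_COLUMN].to_numpy())
    return WeightModel(
        group=group,
        feature_lo=lo_d,
        feature_hi=hi_d,
        y_lo=y_lo,
        y_hi=y_hi,
        C=C,
        gamma=float(svr._gamma) if hasattr(svr, "_gamma") else float("nan"),
        epsilon=epsilon,
        svr=svr,
        cv_metrics=cv,
        cv_rmse_grams=cv.rmse * (y_hi - y_lo),
    )


for _name in ("lstm", "bilstm", "optuna_lstm", "woa_bilstm_attention"):
    MODEL_REGISTRY[_name] = _unavailable(_name)
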