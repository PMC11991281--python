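"""Regression benchmarking over incrementally added ranked features.

Eight regressors are compared: polynomial regression (PR, degree-2
expansion solved by pseudoinverse so collinear designs degrade gracefully),
partial least squares (PLSR), lasso (LR), ridge (RR), decision tree (DTR),
random forest (RFR), XGBoost and LightGBM.  Each is tuned by exhaustive
grid search over its published hyperparameter grid with 3-fold
cross-validation; the selection criterion is mean CV R^2.  Reported
accuracy is the mean over the CV folds.

The parsimony rule: take the best R^2 over the accuracy curve, set the
threshold at 95% of it, and pick the smallest feature count whose R^2
clears the threshold — trading a bounded accuracy loss for far fewer
variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.preprocessing import PolynomialFeatures
from sklearn.tree import DecisionTreeRegressor

from .ranking import RankingResult

logger = logging.getLogger(__name__)

MODEL_NAMES = ("PR", "PLSR", "LR", "RR", "DTR", "RFR", "XGBoost", "LightGBM")

_ALPHAS = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)
_LEARNING_RATES = (0.001, 0.005, 0.01, 0.05, 0.1)
_N_ESTIMATORS = tuple(range(50, 151, 25))


def default_grid(name: str, n_features: int) -> list[dict]:
    """Published hyperparameter grid for each model.

    Integer ranges without a stated increment are enumerated at step 1.
    PLSR components run from 2 to the feature count (a single 1-component
    entry when only one feature is available, so k=1 sweep points exist).
    """
    if name == "PR":
        return [{"degree": 2}]
    if name == "PLSR":
        if n_features < 2:
            return [{"n_components": 1}]
        return [{"n_components": c} for c in range(2, n_features + 1)]
    if name in ("LR", "RR"):
        return [{"alpha": a} for a in _ALPHAS]
    if name == "DTR":
        return [{"max_depth": d, "min_samples_split": s}
                for d in range(4, 101) for s in range(5, 51, 5)]
    if name == "RFR":
        return [{"n_estimators": n, "max_depth": d, "min_samples_split": s}
                for n in _N_ESTIMATORS for d in range(3, 51) for s in range(5, 51, 5)]
    if name == "XGBoost":
        return [{"max_depth": d, "learning_rate": lr, "n_estimators": n}
                for d in range(3, 26) for lr in _LEARNING_RATES for n in _N_ESTIMATORS]
    if name == "LightGBM":
        return [{"num_leaves": nl, "learning_rate": lr, "n_estimators": n}
                for nl in range(50, 151, 10) for lr in _LEARNING_RATES for n in _N_ESTIMATORS]
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


@dataclass
class ModelSpec:
    """A model name plus its hyperparameter grid (default: the published
    grid) and the seed used for fold shuffling and stochastic learners."""

    name: str
    grid: list[dict] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    def resolved_grid(self, n_features: int) -> list[dict]:
        return self.grid if self.grid is not None else default_grid(self.name, n_features)


class _PinvLinearRegression:
    """Least-squares linear fit via SVD pseudoinverse; rank-deficient
    designs return the minimum-norm solution with a conditioning warning."""

    def fit(self, X, y):
        X = np.asarray(X, float)
        A = np.column_stack([np.ones(len(X)), X])
        coef, _, rank, _ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
        if rank < A.shape[1]:
            warnings.warn("rank-deficient polynomial design; minimum-norm solution used",
                          stacklevel=2)
        self.coef_ = coef
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        return np.column_stack([np.ones(len(X)), X]) @ self.coef_


class _PolynomialRegression:
    def __init__(self, degree: int = 2):
        self.poly = PolynomialFeatures(degree=degree, include_bias=False)
        self.lin = _PinvLinearRegression()

    def fit(self, X, y):
        self.lin.fit(self.poly.fit_transform(X), y)
        return self

    def predict(self, X):
        return self.lin.predict(self.poly.transform(X))


def make_estimator(name: str, params: dict, seed: int = 0):
    """Instantiate one estimator from a grid entry."""
    if name == "PR":
        return _PolynomialRegression(**params)
    if name == "PLSR":
        return PLSRegression(n_components=params["n_components"], scale=True)
    if name == "LR":
        if params["alpha"] == 0:
            return LinearRegression()
        return Lasso(alpha=params["alpha"], max_iter=50000)
    if name == "RR":
        if params["alpha"] == 0:
            return LinearRegression()
        return Ridge(alpha=params["alpha"])
    if name == "DTR":
        return DecisionTreeRegressor(random_state=seed, **params)
    if name == "RFR":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "XGBoost":
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                            tree_method="hist", **params)
    if name == "LightGBM":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1,
                             min_child_samples=5, **params)
    raise ValueError(f"unknown model {name!r}")


@dataclass
class EvalMetrics:
    """R^2 = 1 - SS_res/SS_tot, RMSE and MAE on (measured, predicted)."""

    R2: float
    RMSE: float
    MAE: float
    n: int


def eval_metrics(y_measured, y_predicted) -> EvalMetrics:
    ym = np.asarray(y_measured, float)
    yp = np.asarray(y_predicted, float).reshape(ym.shape)
    if ym.size < 2:
        raise ValueError("need n >= 2")
    resid = ym - yp
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((ym - ym.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant measurements: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return EvalMetrics(R2=r2, RMSE=rmse, MAE=mae, n=ym.size)


@dataclass
class FitResult:
    model: str
    best_params: dict
    cv_R2: float
    cv_RMSE: float
    cv_MAE: float
    fold_metrics: list[EvalMetrics]
    skipped: list[dict] = field(default_factory=list)


def _cv_score(est_factory, X: np.ndarray, y: np.ndarray, folds) -> list[EvalMetrics]:
    out = []
    for tr, va in folds:
        est = est_factory()
        est.fit(X[tr], y[tr])
        pred = np.asarray(est.predict(X[va]), float).reshape(-1)
        out.append(eval_metrics(y[va], pred))
    return out


def fit_model(features: pd.DataFrame, y, spec: ModelSpec,
              cv_folds: int = 3, seed: int | None = None) -> FitResult:
    """Exhaustive grid search with k-fold CV; criterion = mean CV R^2.

    Fold assignment is shuffled once from the seed and shared by every grid
    entry.  Infeasible entries (e.g. PLSR components exceeding the training
    sample count) are skipped and logged, not fatal.
    """
    X = features.to_numpy(float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3 * cv_folds:
        raise ValueError(f"need n >= {3 * cv_folds} samples for {cv_folds}-fold CV")
    seed = spec.seed if seed is None else seed
    folds = list(KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(X))
    best, skipped = None, []
    for params in spec.resolved_grid(X.shape[1]):
        if spec.name == "PLSR":
            min_train = min(len(tr) for tr, _ in folds)
            if params["n_components"] > min(X.shape[1], min_train - 1):
                skipped.append(params)
                continue
        try:
            fm = _cv_score(lambda: make_estimator(spec.name, params, seed), X, y, folds)
        except (ValueError, np.linalg.LinAlgError):
            logger.warning("grid entry %s infeasible for %s; skipped", params, spec.name)
            skipped.append(params)
            continue
        mean_r2 = float(np.mean([m.R2 for m in fm]))
        if best is None or mean_r2 > best[0]:
            best = (mean_r2, params, fm)
    if best is None:
        raise ValueError(f"no feasible grid entry for {spec.name}")
    mean_r2, params, fm = best
    return FitResult(
        model=spec.name, best_params=dict(params), cv_R2=mean_r2,
        cv_RMSE=float(np.mean([m.RMSE for m in fm])),
        cv_MAE=float(np.mean([m.MAE for m in fm])),
        fold_metrics=fm, skipped=skipped,
    )


@dataclass
class AccuracyCurve:
    """CV accuracy as a function of the number of top-ranked features."""

    ranking_method: str
    model: str
    target: str
    entries: list[dict]  # {"k", "features", "best_params", "R2", "RMSE", "MAE"}

    def r2_by_k(self) -> dict[int, float]:
        return {e["k"]: e["R2"] for e in self.entries}

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries)
        df.insert(0, "target", self.target)
        df.insert(0, "model", self.model)
        df.insert(0, "ranking", self.ranking_method)
        return df


def incremental_sweep(table: pd.DataFrame, y, ranking: RankingResult,
                      spec: ModelSpec, cv_folds: int = 3, seed: int | None = None,
                      max_k: int | None = None, target: str = "") -> AccuracyCurve:
    """Refit with the top-k ranked features for k = 1..K (full grid search
    at every k) and record CV metrics."""
    missing = set(ranking.features) - set(table.columns)
    if missing:
        raise ValueError(f"ranking references absent features: {sorted(missing)}")
    K = min(max_k or len(ranking.features), len(ranking.features))
    entries = []
    for k in range(1, K + 1):
        feats = ranking.top(k)
        res = fit_model(table[feats], y, spec, cv_folds=cv_folds, seed=seed)
        entries.append({"k": k, "features": feats, "best_params": res.best_params,
                        "R2": res.cv_R2, "RMSE": res.cv_RMSE, "MAE": res.cv_MAE})
    return AccuracyCurve(ranking_method=ranking.method, model=spec.name,
                         target=target, entries=entries)


@dataclass
class ParsimonySelection:
    """Outcome of the 95%-of-best rule on one accuracy curve."""

    n_best: int
    best_R2: float
    threshold: float
    n_reduced: int
    reduced_R2: float

    @property
    def variables_saved(self) -> int:
        return self.n_best - self.n_reduced


def parsimony_select(curve, fraction: float = 0.95) -> ParsimonySelection:
    """Smallest feature count whose R^2 reaches ``fraction`` of the best.

    ``curve`` is an :class:`AccuracyCurve` or a mapping k -> R^2.
    """
    r2 = curve.r2_by_k() if isinstance(curve, AccuracyCurve) else dict(curve)
    if not r2:
        raise ValueError("empty accuracy curve")
    ks = sorted(r2)
    n_best = max(ks, key=lambda k: (r2[k], -k))
    best = r2[n_best]
    threshold = fraction * best
    # when best <= 0 the fractional threshold exceeds the best value and the
    # rule degenerates; keep the full best-point selection in that case
    n_reduced = next((k for k in ks if r2[k] >= threshold), n_best)
    return ParsimonySelection(n_best=n_best, best_R2=best, threshold=threshold,
                              n_reduced=n_reduced, reduced_R2=r2[n_reduced])


def best_combination(curves: list[AccuracyCurve]) -> pd.DataFrame:
    """Summary of each curve's best point (feature count, metrics)."""
    rows = []
    for c in curves:
        sel = parsimony_select(c)
        at_best = next(e for e in c.entries if e["k"] == sel.n_best)
        rows.append({
            "target": c.target, "ranking": c.ranking_method, "model": c.model,
            "best_R2": sel.best_R2, "RMSE": at_best["RMSE"], "MAE": at_best["MAE"],
            "n_best": sel.n_best, "threshold": sel.threshold,
            "n_reduced": sel.n_reduced, "reduced_R2": sel.reduced_R2,
        })
    return pd.DataFrame(rows)
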