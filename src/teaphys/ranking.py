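"""Rank image indices against a physiological target three ways.

* PCA — Pearson correlation analysis: rank by |r| (linear association).
* MRMR — minimum-redundancy maximum-relevance: greedy mutual-information
  selection; at step m the chosen feature maximizes
  I(x_j, y) - (1/(m-1)) * sum_{x_i in S} I(x_j, x_i).
* GRA — gray relational analysis: min-max normalize every sequence, then
  score each feature by its mean gray relational coefficient against the
  target, gamma_i = mean_k (dmin + rho*dmax) / (d_i(k) + rho*dmax), with
  dmin/dmax the global extrema of |feature - target| over ALL features and
  points and rho the distinguishing coefficient (0.5 by convention).

Mutual information uses equal-frequency discretization with ceil(n^(1/3))
bins and plug-in entropy (in nats).  Equal-frequency binning is robust to
the skewed distributions spectral indices often have; the cube-root bin
count keeps the plug-in estimator's bias ((bins-1)^2 / 2n nats) and
variance small enough that weakly relevant features still outrank noise.
All rankings break ties stably by input column order for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

METHODS = ("PCA", "MRMR", "GRA")


class UndefinedCorrelationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class RankingResult:
    """Ordered features with per-feature scores for one ranking method.

    ``scores`` is keyed by feature name: |r| for PCA, the greedy objective at
    selection time for MRMR, and the gray correlation degree for GRA.
    """

    method: str
    features: list[str]
    scores: dict[str, float]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "method": self.method,
            "rank": np.arange(1, len(self.features) + 1),
            "feature": self.features,
            "score": [self.scores[f] for f in self.features],
        })

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def pearson_r(x, y) -> float:
    """Pearson's r between two equal-length series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series with n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def _equal_frequency_bins(v: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into up to ``bins`` classes of near-equal occupancy."""
    if np.all(v == v[0]):
        return np.zeros(v.size, dtype=int)
    edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, v, side="left")


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in MI (nats) of the equal-frequency-discretized joint
    distribution; symmetric, >= 0, and exactly 0 for a constant argument."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10 or y.size != n:
        raise ValueError("need equal-length vectors with n >= 10")
    bins = bins if bins is not None else max(4, math.ceil(n ** (1.0 / 3.0)))
    if bins < 2:
        raise ValueError("bins must be >= 2")
    xi = _equal_frequency_bins(x, bins)
    yi = _equal_frequency_bins(y, bins)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def _stable_desc_order(names: list[str], score: dict[str, float]) -> list[str]:
    # stable sort: equal scores keep input order
    order = np.argsort([-score[n] for n in names], kind="stable")
    return [names[i] for i in order]


def pca_rank(table: pd.DataFrame, y) -> RankingResult:
    """Rank by |Pearson r| with the target, descending."""
    y = np.asarray(y, dtype=float)
    scores = {c: abs(pearson_r(table[c].to_numpy(float), y)) for c in table.columns}
    return RankingResult("PCA", _stable_desc_order(list(table.columns), scores), scores)


def mrmr_rank(table: pd.DataFrame, y, bins: int | None = None) -> RankingResult:
    """Greedy MRMR ordering of all features.

    The first feature maximizes relevance I(x_j, y); each later pick
    maximizes relevance minus mean redundancy to the already-selected set.
    Negative objectives are allowed — selection proceeds regardless of sign.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("MRMR needs at least 2 features")
    y = np.asarray(y, dtype=float)
    X = {c: table[c].to_numpy(float) for c in cols}
    relevance = {c: mutual_information(X[c], y, bins) for c in cols}
    redundancy: dict[tuple[str, str], float] = {}

    def red(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in redundancy:
            redundancy[key] = mutual_information(X[a], X[b], bins)
        return redundancy[key]

    selected: list[str] = []
    scores: dict[str, float] = {}
    pool = list(cols)
    while pool:
        if not selected:
            obj = {c: relevance[c] for c in pool}
        else:
            obj = {c: relevance[c] - sum(red(c, s) for s in selected) / len(selected)
                   for c in pool}
        best = max(pool, key=lambda c: (obj[c], -pool.index(c)))
        scores[best] = obj[best]
        selected.append(best)
        pool.remove(best)
    return RankingResult("MRMR", selected, scores)


def _minmax(v: np.ndarray) -> np.ndarray:
    rng = v.max() - v.min()
    if rng == 0:
        return np.zeros_like(v)
    return (v - v.min()) / rng


def gra_rank(table: pd.DataFrame, y, rho: float = 0.5) -> RankingResult:
    """Gray correlation degree of every feature against the target."""
    if table.shape[1] < 1 or len(table) < 2:
        raise ValueError("need >= 1 feature and n >= 2")
    y = np.asarray(y, dtype=float)
    if y.max() == y.min():
        raise DegenerateInputError("target is constant after normalization")
    yn = _minmax(y)
    deltas = {c: np.abs(_minmax(table[c].to_numpy(float)) - yn) for c in table.columns}
    all_d = np.concatenate(list(deltas.values()))
    dmin, dmax = float(all_d.min()), float(all_d.max())
    scores = {}
    for c, d in deltas.items():
        if dmax == 0.0:  # every sequence matches the target exactly
            grc = np.ones_like(d)
        else:
            grc = (dmin + rho * dmax) / (d + rho * dmax)
        scores[c] = float(grc.mean())
    return RankingResult("GRA", _stable_desc_order(list(table.columns), scores), scores)


def rank_features(table: pd.DataFrame, y, method: str, **kwargs) -> RankingResult:
    """Dispatch to one of the three ranking methods (PCA | MRMR | GRA)."""
    if method == "PCA":
        return pca_rank(table, y)
    if method == "MRMR":
        return mrmr_rank(table, y, **kwargs)
    if method == "GRA":
        return gra_rank(table, y, **kwargs)
    raise ValueError(f"unknown ranking method {method!r}; choose from {METHODS}")


def score_matrix(table: pd.DataFrame, y, methods=METHODS, **kwargs) -> pd.DataFrame:
    """Feature x method score table (heatmap-ready)."""
    out = {}
    for m in methods:
        res = rank_features(table, y, m, **kwargs)
        out[m] = pd.Series(res.scores)
    return pd.DataFrame(out).loc[list(table.columns)]
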