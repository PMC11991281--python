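"""Descriptive and inferential statistics over DSZ tables.

Covers the field-survey reporting conventions: per-parameter descriptive
rows (n, min, mean, max, sample sd, CV = sd/mean) split by farming method;
two-sample comparisons of farming methods at each elevation (Student t or
Welch t, gated by a Levene pre-test on medians at alpha = 0.05); one-way
comparisons across elevations (ANOVA + Tukey HSD under variance
homogeneity, Welch ANOVA + Games-Howell otherwise) compressed into a
compact letter display; and grouped residual reports (RMSE and signed bias
per elevation x season x farming-method cell).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class DescriptiveStats:
    parameter: str
    farming_method: str
    n: int
    min: float
    mean: float
    max: float
    stdev: float
    cv: float  # NaN when the mean is zero

    def row(self) -> dict:
        return self.__dict__.copy()


def describe(table: pd.DataFrame, parameter: str, farming_method: str) -> DescriptiveStats:
    """Table-2-style descriptive row for one parameter under one method.

    Uses the sample standard deviation (n-1 denominator); missing values are
    excluded from n.
    """
    v = table.loc[table["farming_method"] == farming_method, parameter].dropna().to_numpy(float)
    if v.size < 2:
        raise ValueError("need >= 2 non-missing values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        logger.warning("mean is zero: CV undefined for %s/%s", parameter, farming_method)
        cv = float("nan")
    else:
        cv = sd / mean
    return DescriptiveStats(parameter, farming_method, int(v.size),
                            float(v.min()), mean, float(v.max()), sd, cv)


def coefficient_of_variation(mean: float, stdev: float) -> float:
    """CV = StDev / Mean (undefined for a zero mean)."""
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return stdev / mean


def descriptive_table(table: pd.DataFrame, parameters=("LAI", "PRI", "PhiPSII"),
                      methods=("CFM", "AFM")) -> pd.DataFrame:
    rows = [describe(table, p, m).row() for p in parameters for m in methods
            if (table["farming_method"] == m).sum() >= 2]
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Outcome of a grouped comparison: which test ran, its p-value(s),
    significance at alpha = 0.05, and (for >2 groups) letter groups —
    groups sharing a letter are not significantly different."""

    grouping: str
    test: str
    levene_p: float
    p_value: float
    significant: bool
    letters: dict[str, str] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    group_means: dict[str, float] = field(default_factory=dict)


def _groups(table: pd.DataFrame, parameter: str, by: str,
            subset: pd.Series | None = None) -> dict[str, np.ndarray]:
    df = table if subset is None else table[subset]
    out = {}
    for name, sub in df.groupby(by, observed=True):
        v = sub[parameter].dropna().to_numpy(float)
        if v.size:
            out[str(name)] = v
    return out


def compare_farming_methods(table: pd.DataFrame, parameter: str,
                            elevation: str | None = None) -> GroupComparison:
    """CFM vs AFM two-sample t-test (optionally within one elevation class).

    A Levene pre-test on medians decides between the pooled-variance Student
    t and the Welch t; significance is flagged at p < 0.05.
    """
    subset = None if elevation is None else (table["elevation_class"] == elevation)
    groups = _groups(table, parameter, "farming_method", subset)
    if len(groups) != 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need both farming methods with n >= 2 each")
    a, b = groups.values()
    lev_p = float(stats.levene(a, b, center="median").pvalue)
    equal_var = lev_p >= ALPHA
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        grouping=f"farming_method@{elevation or 'all'}",
        test="student_t" if equal_var else "welch_t",
        levene_p=lev_p, p_value=float(t.pvalue),
        significant=bool(t.pvalue < ALPHA),
        group_means={k: float(v.mean()) for k, v in groups.items()},
    )


def _letter_display(names: list[str], nonsig: pd.DataFrame,
                    means: dict[str, float]) -> dict[str, str]:
    """Compact letter display from a pairwise nonsignificance matrix.

    Letters label maximal cliques of the 'not significantly different'
    graph, ordered by descending best group mean; each group inherits the
    letters of every clique it belongs to.
    """
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if nonsig.loc[a, b]:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g), key=lambda c: -max(means[m] for m in c))
    letters = {n: "" for n in names}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for n in clique:
            letters[n] += letter
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def compare_elevations(table: pd.DataFrame, parameter: str,
                       farming_method: str | None = None) -> GroupComparison:
    """One-way comparison of the parameter across elevation classes.

    Levene (medians) gates the omnibus test: classical ANOVA with Tukey HSD
    post hoc under homogeneity, Welch ANOVA with Games-Howell otherwise.
    The pairwise significance matrix is compressed to letter groups.
    """
    subset = None if farming_method is None else (table["farming_method"] == farming_method)
    groups = _groups(table, parameter, "elevation_class", subset)
    if len(groups) < 2 or any(v.size < 3 for v in groups.values()):
        raise ValueError("need >= 2 elevation groups with n >= 3 each")
    names = list(groups)
    arrays = list(groups.values())
    lev_p = float(stats.levene(*arrays, center="median").pvalue)
    homogeneous = lev_p >= ALPHA
    df = table if subset is None else table[subset]
    df = df[["elevation_class", parameter]].dropna()
    if homogeneous:
        p = float(stats.f_oneway(*arrays).pvalue)
        test = "anova+tukey"
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(df[parameter], df["elevation_class"], alpha=ALPHA)
        pw = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        pw = pw.rename(columns={"group1": "A", "group2": "B", "p-adj": "p"})
        pw["p"] = pw["p"].astype(float)
    else:
        import pingouin as pg

        p = float(pg.welch_anova(data=df, dv=parameter, between="elevation_class")["p_unc"].iloc[0])
        test = "welch_anova+games_howell"
        gh = pg.pairwise_gameshowell(data=df, dv=parameter, between="elevation_class")
        pw = gh.rename(columns={"A": "A", "B": "B", "pval": "p"})[["A", "B", "p"]]
    nonsig = pd.DataFrame(True, index=names, columns=names)
    for _, r in pw.iterrows():
        flag = r["p"] >= ALPHA
        nonsig.loc[str(r["A"]), str(r["B"])] = flag
        nonsig.loc[str(r["B"]), str(r["A"])] = flag
    means = {k: float(v.mean()) for k, v in groups.items()}
    letters = _letter_display(names, nonsig, means)
    return GroupComparison(
        grouping=f"elevation@{farming_method or 'all'}",
        test=test, levene_p=lev_p, p_value=p, significant=bool(p < ALPHA),
        letters=letters, pairwise=pw, group_means=means,
    )


def grouped_error_report(predictions: pd.DataFrame,
                         residual_col: str = "residual",
                         by: tuple[str, ...] = ("elevation_class", "season", "farming_method"),
                         ) -> pd.DataFrame:
    """RMSE and mean signed error per metadata cell.

    Positive mean error = systematic overestimation (residual = predicted -
    measured).  Empty cells are omitted with a log entry.
    """
    missing = set(by) - set(predictions.columns)
    if missing:
        raise ValueError(f"residual table lacks columns {sorted(missing)}")
    rows = []
    for keys, sub in predictions.groupby(list(by), observed=True):
        r = sub[residual_col].dropna().to_numpy(float)
        if r.size == 0:
            logger.info("empty cell %s omitted", keys)
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append({**dict(zip(by, keys)),
                     "n": int(r.size),
                     "RMSE": float(np.sqrt(np.mean(r ** 2))),
                     "mean_error": float(r.mean()),
                     "direction": "over" if r.mean() > 0 else ("under" if r.mean() < 0 else "unbiased")})
    return pd.DataFrame(rows)
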