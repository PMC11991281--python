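"""Pearson, mutual-information/MRMR and gray relational analysis rankings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import teaphys as tp
from teaphys.ranking import (DegenerateInputError, UndefinedCorrelationError,
                             _equal_frequency_bins, mutual_information)


def brute_force_mrmr(table: pd.DataFrame, y, bins=None):
    """Oracle: evaluate the selection objective exhaustively at every step."""
    pool = list(table.columns)
    sel = []
    mi = {c: mutual_information(table[c], y, bins) for c in pool}
    pair = {}

    def red(a, b):
        k = tuple(sorted((a, b)))
        if k not in pair:
            pair[k] = mutual_information(table[k[0]], table[k[1]], bins)
        return pair[k]

    while pool:
        scores = []
        for c in pool:
            if sel:
                obj = mi[c] - sum(red(c, s) for s in sel) / len(sel)
            else:
                obj = mi[c]
            scores.append(obj)
        best = pool[int(np.argmax(scores))]
        sel.append(best)
        pool.remove(best)
    return sel


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [3, 5, 7], 1.0),
        ([1, 2, 3], [1, 0, 1], 0.0),
        ([1, 2, 3], [-2, -4, -6], -1.0),
    ])
    def test_hand_cases(self, x, y, expected):
        assert tp.pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_error(self):
        with pytest.raises(UndefinedCorrelationError):
            tp.pearson_r([1, 1, 1], [1, 2, 3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r = tp.pearson_r(x, y)
        assert tp.pearson_r(scale * x + shift, y) == pytest.approx(r, abs=1e-9)


class TestMutualInformation:
    def test_symmetry(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_identity_equals_entropy_of_discretized_x(self, rng):
        x = rng.normal(size=400)
        bins = 8
        xi = _equal_frequency_bins(x, bins)
        p = np.bincount(xi) / xi.size
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(x, x.copy(), bins) == pytest.approx(h)

    def test_constant_vector_gives_zero(self, rng):
        assert mutual_information(np.ones(50), rng.normal(size=50)) == 0.0

    def test_independent_below_permutation_null(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        observed = mutual_information(x, y)
        null = [mutual_information(x, rng.permutation(y)) for _ in range(200)]
        assert observed < np.quantile(null, 0.95)


class TestMRMR:
    def test_max_relevance_first(self, rng):
        y = rng.normal(size=120)
        t = pd.DataFrame({"x1": y.copy(), "x2": rng.normal(size=120)})
        assert tp.mrmr_rank(t, y).features[0] == "x1"

    def test_redundancy_penalty_demotes_copy(self, rng):
        # y = u + v; x1 = u (strong), x2 = exact copy of x1 (fully
        # redundant), x3 = v (moderate relevance, independent of x1)
        u = rng.normal(size=200)
        v = 0.6 * rng.normal(size=200)
        y = u + v
        t = pd.DataFrame({"x1": u, "x2": u.copy(), "x3": v})
        order = tp.mrmr_rank(t, y).features
        assert order[0] == "x1"
        assert order[1] == "x3"  # the exact copy x2 is penalized
        assert order == brute_force_mrmr(t, y)

    def test_greedy_equals_brute_force_on_random_tables(self, rng):
        for _ in range(10):
            t = pd.DataFrame(rng.normal(size=(80, 5)),
                             columns=[f"f{i}" for i in range(5)])
            y = t["f0"] * 0.8 + rng.normal(size=80)
            assert tp.mrmr_rank(t, y).features == brute_force_mrmr(t, y)


class TestGRA:
    def test_identical_feature_scores_one(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        t = pd.DataFrame({"x": y * 2 + 1})  # identical after normalization
        res = tp.gra_rank(t, y)
        assert res.scores["x"] == pytest.approx(1.0)

    def test_three_point_worked_example(self):
        # normalized y=(0,0.5,1), x=(1,0.5,0): deltas (1,0,1), GCD = 5/9
        y = np.array([0.0, 0.5, 1.0])
        t = pd.DataFrame({"x": [1.0, 0.5, 0.0]})
        assert tp.gra_rank(t, y).scores["x"] == pytest.approx(5.0 / 9.0)

    def test_lower_bound_when_dmin_zero(self, rng):
        y = rng.normal(size=50)
        t = pd.DataFrame({"same": y.copy(),
                          **{f"n{i}": rng.normal(size=50) for i in range(5)}})
        res = tp.gra_rank(t, y)
        assert all(s >= 1.0 / 3.0 - 1e-12 for s in res.scores.values())
        assert all(0 < s <= 1.0 for s in res.scores.values())

    def test_constant_target_degenerate(self):
        with pytest.raises(DegenerateInputError):
            tp.gra_rank(pd.DataFrame({"x": [1.0, 2.0]}), np.array([3.0, 3.0]))


class TestDispatch:
    def test_unknown_method(self, planted_table):
        table, _ = planted_table
        with pytest.raises(ValueError, match="unknown ranking method"):
            tp.rank_features(table[["NDVI", "GNDVI"]], table["LAI"], "RF")

    def test_all_methods_recover_planted_features(self, planted_table):
        table, truth = planted_table
        causal = truth.causal_features("LAI")
        cols = [c for c in table.columns if c in causal or c.startswith("noise_")]
        for method in tp.ranking.METHODS:
            res = tp.rank_features(table[cols], table["LAI"], method)
            assert all(c in res.top(5) for c in causal), method

    def test_deterministic_and_full_length(self, planted_table):
        table, truth = planted_table
        cols = [c for c in table.columns if c.startswith("noise_")][:6]
        for method in tp.ranking.METHODS:
            a = tp.rank_features(table[cols], table["LAI"], method)
            b = tp.rank_features(table[cols], table["LAI"], method)
            assert a.features == b.features
            assert len(a.features) == len(cols)
            assert len(a.table()) == len(cols)

    def test_noise_feature_preserves_relative_order_pca_gra(self, planted_table):
        table, truth = planted_table
        cols = truth.causal_features("LAI") + [c for c in table.columns
                                               if c.startswith("noise_")][:5]
        extra = cols + [c for c in table.columns if c.startswith("noise_")][5:6]
        for method in ("PCA", "GRA"):
            base = tp.rank_features(table[cols], table["LAI"], method).features
            more = tp.rank_features(table[extra], table["LAI"], method).features
            filtered = [f for f in more if f in cols]
            assert filtered == base, method

    def test_score_matrix_shape(self, planted_table):
        table, truth = planted_table
        cols = [c for c in table.columns if c.startswith("noise_")][:4]
        m = tp.score_matrix(table[cols], table["LAI"])
        assert m.shape == (4, 3)
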