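"""Evaluation metrics, grid-searched CV fitting, incremental sweeps and the
95%-of-best parsimony rule."""

import math

import numpy as np
import pandas as pd
import pytest

import teaphys as tp
from teaphys.modeling import MODEL_NAMES, default_grid
from teaphys.pipeline import FAST_GRIDS


class TestEvalMetrics:
    def test_perfect_prediction(self):
        m = tp.eval_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.R2 == 1.0 and m.RMSE == 0.0 and m.MAE == 0.0

    def test_hand_computed_case(self):
        m = tp.eval_metrics([1, 2, 3], [2, 2, 2])
        assert m.R2 == pytest.approx(0.0)
        assert m.RMSE == pytest.approx(math.sqrt(2.0 / 3.0))
        assert m.MAE == pytest.approx(2.0 / 3.0)

    def test_mean_predictor_gives_zero_r2(self, rng):
        y = rng.normal(size=40)
        m = tp.eval_metrics(y, np.full(40, y.mean()))
        assert m.R2 == pytest.approx(0.0)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(100):
            y = rng.normal(size=25)
            p = rng.normal(size=25)
            m = tp.eval_metrics(y, p)
            assert m.RMSE >= m.MAE >= 0.0

    def test_constant_measurements_warn_nan_r2(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = tp.eval_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(m.R2) and m.RMSE > 0


class TestGrids:
    def test_published_grid_values(self):
        lr = default_grid("LR", 5)
        assert [g["alpha"] for g in lr] == [0, 0.01, 0.1, 1, 10, 100]
        xgb = default_grid("XGBoost", 5)
        assert sorted({g["learning_rate"] for g in xgb}) == [0.001, 0.005, 0.01, 0.05, 0.1]
        assert sorted({g["n_estimators"] for g in xgb}) == [50, 75, 100, 125, 150]
        assert sorted({g["max_depth"] for g in xgb}) == list(range(3, 26))
        assert len(default_grid("DTR", 5)) == 97 * 10
        assert len(default_grid("RFR", 5)) == 5 * 48 * 10
        assert len(default_grid("LightGBM", 5)) == 11 * 5 * 5
        assert sorted({g["num_leaves"] for g in default_grid("LightGBM", 5)}) == list(range(50, 151, 10))

    def test_plsr_components_track_feature_count(self):
        assert [g["n_components"] for g in default_grid("PLSR", 6)] == [2, 3, 4, 5, 6]
        assert default_grid("PLSR", 1) == [{"n_components": 1}]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            tp.ModelSpec("SVM")


class TestFitModel:
    def test_noiseless_linear_target_perfect_lr(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = 2.0 + X["a"] - 0.5 * X["b"]
        res = tp.fit_model(X, y, tp.ModelSpec("LR"), seed=0)
        assert res.cv_R2 >= 0.999
        assert res.best_params["alpha"] == 0

    @pytest.mark.parametrize("name", ["PR", "PLSR", "LR", "RR", "DTR"])
    def test_deterministic_models_repeatable(self, name, rng):
        X = pd.DataFrame(rng.normal(size=(45, 4)), columns=list("abcd"))
        y = X["a"] * 2 + rng.normal(scale=0.5, size=45)
        grid = FAST_GRIDS.get(name)
        a = tp.fit_model(X, y, tp.ModelSpec(name, grid=grid), seed=7)
        b = tp.fit_model(X, y, tp.ModelSpec(name, grid=grid), seed=7)
        assert a.best_params == b.best_params
        assert a.cv_R2 == b.cv_R2

    def test_plsr_infeasible_components_skipped(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = X["f0"] + rng.normal(scale=0.1, size=12)
        res = tp.fit_model(X, y, tp.ModelSpec("PLSR"), cv_folds=3, seed=0)
        assert res.skipped  # components > training-fold size are dropped
        assert np.isfinite(res.cv_R2)

    def test_too_few_samples_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(7, 2)), columns=list("ab"))
        with pytest.raises(ValueError, match="need n >="):
            tp.fit_model(X, X["a"], tp.ModelSpec("RR"), cv_folds=3)

    def test_ridge_beats_polynomial_under_collinearity(self, rng):
        # strongly collinear planted design: PR's quadratic expansion
        # overfits while ridge regularizes (20-seed median comparison)
        rr, pr = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            base = r.normal(size=60)
            X = pd.DataFrame({f"x{i}": base + r.normal(scale=0.01, size=60)
                              for i in range(6)})
            y = base + r.normal(scale=0.3, size=60)
            rr.append(tp.fit_model(X, y, tp.ModelSpec("RR"), seed=seed).cv_R2)
            pr.append(tp.fit_model(X, y, tp.ModelSpec("PR"), seed=seed).cv_R2)
        assert np.median(rr) >= np.median(pr)


class TestSweepAndParsimony:
    def test_single_causal_feature_curve_peaks_early(self):
        table, truth = tp.generate_feature_table(
            200, 5,
            truth=tp.TruthModel(coefficients={"LAI": {"intercept": 2.0,
                                                      "weights": {"NDVI": 5.0}}},
                                noise_sd={"LAI": 0.3}),
            seed=0)
        cols = ["NDVI"] + [c for c in table.columns if c.startswith("noise_")]
        ranking = tp.rank_features(table[cols], table["LAI"], "PCA")
        curve = tp.incremental_sweep(table[cols], table["LAI"], ranking,
                                     tp.ModelSpec("RR"), seed=0)
        r2 = curve.r2_by_k()
        assert ranking.features[0] == "NDVI"
        assert r2[1] >= max(r2.values()) - 0.02

    def test_curve_has_no_gaps_and_columns(self, planted_table):
        table, truth = planted_table
        cols = truth.causal_features("LAI") + ["noise_00", "noise_01"]
        ranking = tp.rank_features(table[cols], table["LAI"], "GRA")
        curve = tp.incremental_sweep(table[cols], table["LAI"], ranking,
                                     tp.ModelSpec("RR"), seed=0, target="LAI")
        assert [e["k"] for e in curve.entries] == [1, 2, 3, 4]
        df = curve.table()
        assert set(["ranking", "model", "target", "k", "R2", "RMSE", "MAE"]) <= set(df.columns)

    @pytest.mark.parametrize("curve,expect", [
        ({1: 0.50, 2: 0.69, 3: 0.716}, (3, 0.6802, 2)),
        ({1: 0.8, 2: 0.7, 3: 0.6}, (1, 0.76, 1)),
    ])
    def test_parsimony_rule(self, curve, expect):
        sel = tp.parsimony_select(curve)
        n_best, threshold, n_reduced = expect
        assert sel.n_best == n_best
        assert sel.threshold == pytest.approx(threshold)
        assert sel.n_reduced == n_reduced
        assert sel.reduced_R2 >= sel.threshold
        assert sel.n_reduced <= sel.n_best

    def test_parsimony_threshold_printed_precision(self):
        sel = tp.parsimony_select({1: 0.5, 43: 0.716})
        assert round(sel.threshold, 3) == 0.680

    def test_parsimony_invariants_random_curves(self, rng):
        for _ in range(50):
            curve = {k: float(r) for k, r in
                     enumerate(rng.uniform(0, 1, size=rng.integers(2, 12)), start=1)}
            sel = tp.parsimony_select(curve)
            assert sel.n_reduced <= sel.n_best
            assert sel.reduced_R2 >= 0.95 * sel.best_R2 - 1e-12

    def test_best_combination_summary(self, planted_table):
        table, truth = planted_table
        cols = truth.causal_features("LAI") + ["noise_00"]
        ranking = tp.rank_features(table[cols], table["LAI"], "PCA")
        curve = tp.incremental_sweep(table[cols], table["LAI"], ranking,
                                     tp.ModelSpec("RR"), seed=0, target="LAI")
        summary = tp.best_combination([curve])
        assert len(summary) == 1
        assert summary.loc[0, "n_reduced"] <= summary.loc[0, "n_best"]
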