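"""Random-forest pipeline: splitting, tuning, metrics, importance, PDP."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as sk_permutation_importance

from haiforest.model import (
    RFParams,
    TuningGrid,
    cv_rmse,
    default_grid,
    evaluate,
    fit_rf,
    null_metrics,
    partial_dependence,
    permutation_importance,
    split_train_test,
    tune_rf,
)
from .conftest import toy_regression


class TestSplit:
    def test_published_cohort_split_sizes(self):
        X, y = toy_regression(n=2815, p=3, seed=0)
        Xtr, Xte, ytr, yte = split_train_test(X, y, 0.8, seed=0)
        assert (len(Xtr), len(Xte)) == (2252, 563)

    def test_partition_is_disjoint_and_exhaustive(self):
        X, y = toy_regression(n=101, p=2, seed=1)
        Xtr, Xte, *_ = split_train_test(X, y, 0.8, seed=1)
        assert len(Xtr) + len(Xte) == 101
        assert set(Xtr.index).isdisjoint(Xte.index)

    def test_seed_reproducibility(self):
        X, y = toy_regression(n=50, p=2, seed=2)
        a = split_train_test(X, y, seed=9)
        b = split_train_test(X, y, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert not a[0].index.equals(split_train_test(X, y, seed=10)[0].index)

    def test_too_small(self):
        X, y = toy_regression(n=12, p=2)
        with pytest.raises(ValueError):
            split_train_test(X.head(9), y[:9])


class TestTuning:
    def test_single_combination_returned(self):
        X, y = toy_regression(n=80, p=4, seed=3)
        grid = TuningGrid(mtry=[2], ntree=[30], nodesize=[5], maxnodes=[None], seed=3)
        best, table = tune_rf(X, y, grid)
        assert best == RFParams(2, 30, 5, None)
        assert len(table) == 1

    def test_regularization_wins_on_pure_noise(self):
        """Tiny trees beat unbounded trees by CV RMSE on a signal-free outcome."""
        wins = 0
        for seed in range(10):
            X, y = toy_regression(n=150, p=5, signal=(), noise=1.0, seed=seed)
            grid = TuningGrid(mtry=[2], ntree=[50], nodesize=[5],
                              maxnodes=[4, None], seed=seed)
            best, _ = tune_rf(X, y, grid)
            wins += best.maxnodes == 4
        assert wins >= 8

    def test_signal_beats_null_in_cv(self):
        X, y = toy_regression(n=300, p=6, signal=(0, 1), coef=2.0, noise=1.0, seed=4)
        params = RFParams(mtry=2, ntree=100)
        rf = cv_rmse(X, y, params, seed=4)
        null = float(np.std(y))  # RMSE of predicting the mean
        assert rf < null

    def test_default_grid_shape(self):
        g = default_grid(86)
        assert set(g.mtry) == {9, 28, 43}
        assert len(g.combinations()) == len(g.mtry) * 2 * 2


class TestMetrics:
    def test_null_model_r2_is_zero_by_convention(self):
        y_tr = np.array([1.0, 2.0, 3.0])
        y_te = np.array([0.0, 2.0, 4.0, 1.0])
        m = null_metrics(y_tr, y_te)
        assert m.r2 == 0.0
        assert m.rmse == pytest.approx(np.sqrt(np.mean((y_te - 2.0) ** 2)))

    def test_perfect_predictions(self):
        X, y = toy_regression(n=40, p=2, seed=5)
        class Identity:
            def predict(self, A):
                return y
        m = evaluate(Identity(), X, y)
        assert (m.rmse, m.mae, m.r2) == (0.0, 0.0, 1.0) or (
            m.rmse == 0.0 and m.mae == 0.0 and m.r2 == pytest.approx(1.0)
        )

    def test_constant_residual(self):
        class Shift:
            def predict(self, A):
                return np.zeros(len(A))
        X = pd.DataFrame({"a": np.ones(5)})
        y = np.full(5, 0.7)
        m = evaluate(Shift(), X, y)
        assert m.rmse == pytest.approx(0.7)
        assert m.mae == pytest.approx(0.7)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=200)})
        y = rng.normal(size=200)
        model = fit_rf(X, y, RFParams(mtry=1, ntree=20), seed=6)
        m = evaluate(model, X, y)
        assert m.mae <= m.rmse

    def test_residual_convention_flag(self):
        y_tr = np.array([0.0, 2.0])
        y_te = np.array([0.0, 2.0, 4.0])
        m = null_metrics(y_tr, y_te, r2_convention="residual")
        # predicting 1.0 for (0,2,4): MSE = (1+1+9)/3, Var = 8/3
        assert m.r2 == pytest.approx(1 - (11 / 3) / (8 / 3))

    def test_empty_test_set_errors(self):
        with pytest.raises(ValueError):
            null_metrics(np.array([1.0]), np.array([]))


class TestPermutationImportance:
    def test_matches_sklearn_oracle(self):
        """%IncMSE agrees with sklearn's permutation importance after rescaling."""
        X, y = toy_regression(n=250, p=4, signal=(0, 2), coef=1.5, seed=7)
        model = fit_rf(X, y, RFParams(mtry=2, ntree=100), seed=7)
        ours = permutation_importance(model, X, y, n_repeats=30, seed=7)
        base_mse = np.mean((y - model.predict(X.to_numpy())) ** 2)
        sk = sk_permutation_importance(
            model, X.to_numpy(), y, scoring="neg_mean_squared_error",
            n_repeats=30, random_state=7,
        )
        sk_pct = 100.0 * sk.importances_mean / base_mse
        got = ours.table.set_index("feature")["pct_inc_mse"]
        for j, name in enumerate(X.columns):
            assert got[name] == pytest.approx(sk_pct[j], abs=0.15 * max(1.0, abs(sk_pct[j])))

    def test_unused_feature_has_near_zero_importance(self):
        X, y = toy_regression(n=300, p=2, signal=(0,), coef=3.0, noise=0.5, seed=8)
        X["const"] = 1.0  # never split on -> permuting it changes nothing
        model = fit_rf(X, y, RFParams(mtry=3, ntree=100), seed=8)
        ours = permutation_importance(model, X, y, n_repeats=20, seed=8)
        got = ours.table.set_index("feature")["pct_inc_mse"]
        assert abs(got["const"]) < 1.0
        assert got["f00"] > 10.0

    def test_independent_outcome_importances_near_zero(self):
        """On held-out data (the package's convention) a signal-free outcome
        yields importances scattered around zero with mixed signs."""
        pooled = []
        for seed in (1, 2, 3):
            X, y = toy_regression(n=400, p=5, signal=(), seed=seed)
            Xtr, Xte, ytr, yte = split_train_test(X, y, seed=seed)
            model = fit_rf(Xtr, ytr, RFParams(mtry=2, ntree=50), seed=seed)
            ours = permutation_importance(model, Xte, yte, n_repeats=10, seed=seed)
            vals = ours.table["pct_inc_mse"]
            assert vals.abs().max() < 15.0
            pooled += list(vals)
        assert min(pooled) < 0 < max(pooled)

    def test_planted_dominant_predictor_ranks_first(self):
        hits = 0
        for seed in range(10):
            X, y = toy_regression(n=300, p=10, signal=(0,), coef=3.0, noise=1.0, seed=seed)
            model = fit_rf(X, y, RFParams(mtry=3, ntree=60), seed=seed)
            ours = permutation_importance(model, X, y, n_repeats=3, seed=seed)
            hits += ours.table.iloc[0]["feature"] == "f00"
        assert hits >= 9

    def test_ranks_contiguous_and_sorted(self):
        X, y = toy_regression(n=100, p=6, signal=(1,), seed=10)
        model = fit_rf(X, y, RFParams(mtry=2, ntree=30), seed=10)
        r = permutation_importance(model, X, y, n_repeats=2, seed=10)
        assert list(r.table["rank"]) == list(range(1, 7))
        assert (r.table["pct_inc_mse"].diff().dropna() <= 1e-12).all()

    def test_feature_mismatch_errors(self):
        X, y = toy_regression(n=100, p=3, seed=11)
        model = fit_rf(X, y, RFParams(mtry=1, ntree=10), seed=11)
        with pytest.raises(ValueError):
            permutation_importance(model, X.iloc[:, :2], y, seed=11)


class TestPartialDependence:
    def test_ignored_feature_gives_flat_profile(self):
        X, y = toy_regression(n=300, p=2, signal=(0,), coef=3.0, noise=0.3, seed=12)
        X["const"] = 0.5
        model = fit_rf(X, y, RFParams(mtry=3, ntree=50), seed=12)
        prof = partial_dependence(model, X, "const", grid=np.linspace(0, 1, 10))
        assert prof.average_prediction.max() - prof.average_prediction.min() < 1e-9

    def test_stump_gives_two_level_step_at_threshold(self):
        """A depth-1 tree splitting x at t yields a step profile: the two levels
        are the leaf means, and the jump happens at t (hand-computable)."""
        x = np.concatenate([np.zeros(50), np.ones(50)])
        y = np.concatenate([np.full(50, 1.0), np.full(50, 5.0)])
        X = pd.DataFrame({"x": x})
        stump = RandomForestRegressor(
            n_estimators=1, max_leaf_nodes=2, bootstrap=False, random_state=0
        ).fit(X, y)
        prof = partial_dependence(stump, X, "x", grid=np.array([0.0, 0.25, 0.75, 1.0]))
        assert np.allclose(prof.average_prediction, [1.0, 1.0, 5.0, 5.0])

    def test_monotone_truth_gives_positive_spearman(self):
        X, y = toy_regression(n=400, p=3, signal=(0,), coef=2.0, noise=0.5, seed=13)
        model = fit_rf(X, y, RFParams(mtry=2, ntree=80), seed=13)
        prof = partial_dependence(model, X, "f00")
        rho, _ = spearmanr(prof.grid, prof.average_prediction)
        assert rho > 0.9

    def test_default_grid_spans_inner_percentiles(self):
        X, y = toy_regression(n=500, p=2, seed=14)
        model = fit_rf(X, y, RFParams(mtry=1, ntree=10), seed=14)
        prof = partial_dependence(model, X, "f01")
        assert prof.grid.size == 25
        lo, hi = np.quantile(X["f01"], [0.05, 0.95])
        assert prof.grid[0] == pytest.approx(lo) and prof.grid[-1] == pytest.approx(hi)

    def test_empty_grid_errors(self):
        X, y = toy_regression(n=100, p=2, seed=15)
        model = fit_rf(X, y, RFParams(mtry=1, ntree=10), seed=15)
        with pytest.raises(ValueError):
            partial_dependence(model, X, "f00", grid=np.array([]))


def test_reproducibility_end_to_end():
    """Same seed + data + params -> identical split, fit and importances."""
    X, y = toy_regression(n=200, p=5, signal=(0,), seed=16)
    out = []
    for _ in range(2):
        Xtr, Xte, ytr, yte = split_train_test(X, y, seed=16)
        model = fit_rf(Xtr, ytr, RFParams(mtry=2, ntree=40), seed=16)
        imp = permutation_importance(model, Xte, yte, n_repeats=3, seed=16)
        out.append((evaluate(model, Xte, yte).rmse, tuple(imp.table["pct_inc_mse"])))
    assert out[0] == out[1]
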