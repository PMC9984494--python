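"""Split discipline, hyperparameter search, early stopping, skill metric,
and Shapley attribution of the boosted-tree protocol."""

import numpy as np
import pandas as pd
import pytest

from cropclimex import yield_model as ym


class TestSplitPlan:
    def test_balanced_sizes_28_years(self):
        plan = ym.make_split_plan(np.arange(28), seed=0)
        assert sorted(len(g) for g in plan.groups) == [7, 7, 7, 7]

    def test_balanced_sizes_30_years(self):
        plan = ym.make_split_plan(np.arange(30), seed=0)
        assert sorted(len(g) for g in plan.groups) == [7, 7, 8, 8]

    def test_same_seed_same_plan(self):
        p1 = ym.make_split_plan(np.arange(30), seed=5)
        p2 = ym.make_split_plan(np.arange(30), seed=5)
        assert p1 == p2

    def test_every_year_held_out_once_and_roles_disjoint(self):
        plan = ym.make_split_plan(np.arange(30), seed=3)
        held_all = []
        for fold in range(4):
            train, eval_, held = plan.fold_roles(fold)
            assert not (set(train) & set(held))
            assert not (set(eval_) & set(held))
            assert not (set(train) & set(eval_))
            held_all.extend(held)
        assert sorted(held_all) == list(range(30))

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            ym.make_split_plan(np.arange(6), seed=0)


class TestHyperparameters:
    def test_sampler_stays_in_boxes(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            cand = ym.sample_hyperparameters(rng)
            for name, (lo, hi) in ym.HYPERPARAM_BOXES.items():
                assert lo <= cand[name] <= hi

    def test_tuning_returns_box_member_deterministically(self):
        rng = np.random.default_rng(2)
        n = 300
        X = rng.normal(size=(n, 4))
        y = 0.2 * X[:, 0] + rng.normal(0, 0.1, n)
        years = rng.integers(0, 10, n)
        p1 = ym.tune_hyperparameters(X, y, years, n_iter=3, rng=7, n_trees=50)
        p2 = ym.tune_hyperparameters(X, y, years, n_iter=3, rng=7, n_trees=50)
        assert p1 == p2
        for name, (lo, hi) in ym.HYPERPARAM_BOXES.items():
            assert lo <= p1[name] <= hi

    def test_too_few_years_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            ym.tune_hyperparameters(X, np.zeros(10), np.zeros(10), rng=0)


class TestEarlyStopping:
    def test_noise_response_stops_early(self):
        """On pure noise the evaluation error cannot keep improving, so
        boosting halts well before the 400-tree cap in >= 9/10 runs."""
        stopped = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 6))
            y = rng.normal(size=400)
            Xe = rng.normal(size=(200, 6))
            ye = rng.normal(size=200)
            _, best_it = ym.fit_fold(
                X, y, Xe, ye, {"subsample": 0.8, "colsample_bytree": 0.8,
                               "reg_lambda": 1.0, "gamma": 0.0}, seed=seed,
            )
            if best_it + 1 < 400 - 40:
                stopped += 1
        assert stopped >= 9

    def test_predictable_response_fits_signal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(600, 4))
        w = np.array([0.5, -0.3, 0.2, 0.0])
        y = X @ w
        booster, best_it = ym.fit_fold(
            X[:400], y[:400], X[400:], y[400:],
            {"subsample": 1.0, "colsample_bytree": 1.0, "reg_lambda": 1.0,
             "gamma": 0.0}, seed=0,
        )
        import xgboost as xgb

        pred = booster.predict(xgb.DMatrix(X[400:]), iteration_range=(0, best_it + 1))
        rmse = np.sqrt(np.mean((pred - y[400:]) ** 2))
        assert rmse < 0.35 * y.std()

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            ym.fit_fold(np.zeros((0, 2)), np.zeros(0), np.zeros((5, 2)),
                        np.zeros(5), {})


class TestExplainedVariance:
    def test_identity_is_plus_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        years = np.repeat(np.arange(20), 5)
        assert ym.explained_variance(a, a, years) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        years = np.repeat(np.arange(20), 5)
        assert ym.explained_variance(a, -a, years) == pytest.approx(-1.0)

    def test_constructed_half_correlation(self):
        """Series built with exact Pearson r = 0.5 give signed r^2 = +0.25."""
        rng = np.random.default_rng(1)
        z1 = rng.normal(size=200)
        z2 = rng.normal(size=200)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # orthogonalize
        z2 /= z2.std()
        b = 0.5 * z1 + np.sqrt(1 - 0.25) * z2
        got = ym.explained_variance(z1, b, aggregation="none")
        assert got == pytest.approx(0.25, abs=1e-9)

    def test_weighted_aggregation(self):
        # two cells per year; weight 1 cell to zero -> aggregate equals other
        years = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        a = np.array([1.0, 9.0, 2.0, 9.0, 3.0, 9.0, 4.0, 9.0])
        b = np.array([1.0, -9.0, 2.0, -9.0, 3.0, -9.0, 4.0, -9.0])
        w = np.array([1.0, 0.0] * 4)
        assert ym.explained_variance(a, b, years, weights=w) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ym.explained_variance(np.ones(2), np.ones(2), aggregation="none")


def _toy_run(n_cells=40, n_years=16, seed=0, beta=(-0.05, -0.03), n_repeats=2):
    """Small fitted run on a linear synthetic response."""
    rng = np.random.default_rng(seed)
    cells, years = np.meshgrid(np.arange(n_cells), np.arange(n_years), indexing="ij")
    n = cells.size
    data = pd.DataFrame({"cell": cells.ravel(), "year": years.ravel()})
    for col in ym.DEFAULT_FEATURES:
        data[col] = rng.normal(size=n)
    data["anomaly"] = (
        beta[0] * data["hot_days"]
        + beta[1] * data["dry_days"]
        + rng.normal(0, 0.01, n)
    )
    run = ym.run_model(data, n_repeats=n_repeats, seed=seed)
    return data, run


class TestPredictionsAndAttribution:
    def test_out_of_sample_panel_is_continuous(self):
        data, run = _toy_run()
        for rep in run.repeats:
            got = rep.predictions.sort_values(["cell", "year"])
            assert len(got) == len(data)
            # prediction for each year comes from the fold holding that year out
            for fold in rep.folds:
                assert not (set(fold.held_years) & set(fold.train_years))

    def test_attribution_additivity(self):
        data, run = _toy_run()
        fold = run.repeats[0].folds[0]
        X = data[run.feature_names].to_numpy(float)[:100]
        contrib = ym.shap_contributions(fold, X)
        pred = fold.predict(X)
        assert np.allclose(contrib.sum(axis=1), pred, atol=1e-5)

    def test_attribution_concentrates_on_informative_features(self):
        data, run = _toy_run(seed=3)
        shap = ym.attribute_features(run, data, seed=0)
        informative = shap[["hot_days", "dry_days"]].sum()
        idle = shap[["cold_days", "wet_days", "mean_temp", "mean_sm",
                     "gs_precip", "annual_precip"]].sum()
        assert informative > 5 * idle

    def test_single_feature_model_gets_all_attribution(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({
            "cell": np.repeat(np.arange(30), 12),
            "year": np.tile(np.arange(12), 30),
        })
        for col in ym.DEFAULT_FEATURES:
            data[col] = 0.0
        data["hot_days"] = rng.normal(size=len(data))
        data["anomaly"] = -0.06 * data["hot_days"]
        run = ym.run_model(data, n_repeats=1, seed=1)
        shap = ym.attribute_features(run, data, seed=0)
        assert shap["hot_days"] > 0
        assert shap.drop("hot_days").abs().max() == pytest.approx(0.0, abs=1e-12)
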