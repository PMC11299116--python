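"""Metrics, model suite, grid search, sensitivity, descriptive shares."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures
from sklearn.tree import DecisionTreeRegressor

from heatlag.prediction import (
    EvalReport,
    RFSpec,
    SplitSpec,
    descriptive_shares,
    evaluate,
    fit_predict_suite,
    grid_search,
    pearson_correlations,
    sensitivity_analysis,
    shares_from_totals,
    _rolling_arima,
)
from heatlag.reference import MONTHLY_COUNTS, SANFU_COUNTS


class TestEvaluate:
    def test_perfect_prediction(self):
        assert evaluate([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 1.0)

    def test_hand_computed_example(self):
        mse, rmse, r2 = evaluate([1, 2, 3], [1, 2, 4])
        assert mse == pytest.approx(1 / 3)
        assert rmse == pytest.approx(np.sqrt(1 / 3))
        assert r2 == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_rmse_squared_is_mse_and_sklearn_agrees(self, seed):
        rng = np.random.default_rng(seed)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        mse, rmse, r2 = evaluate(y, yhat)
        assert rmse**2 == pytest.approx(mse, abs=1e-9)
        assert mse == pytest.approx(mean_squared_error(y, yhat))
        assert r2 == pytest.approx(r2_score(y, yhat))

    def test_constant_observations_reported(self):
        with pytest.warns(UserWarning, match="constant"):
            _, _, r2 = evaluate([2, 2, 2], [1, 2, 3])
        assert np.isnan(r2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 2, 3], [1, 2])


class TestShares:
    def test_monthly_reference_shares(self):
        shares = shares_from_totals(MONTHLY_COUNTS)
        assert shares["july"] == 59.14
        assert shares["august"] == 32.59
        assert shares["june"] == 6.01

    def test_sanfu_reference_shares(self):
        shares = shares_from_totals(SANFU_COUNTS)
        assert shares["zhongfu"] == 54.99
        assert shares["toufu"] == 16.46
        assert shares["non_sanfu"] == 20.88
        assert shares["mofu"] == 7.66

    def test_single_group_is_one_hundred(self):
        assert shares_from_totals({"only": 37})["only"] == 100.00

    def test_zero_total_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            shares_from_totals({"a": 0, "b": 0})

    @pytest.mark.parametrize("seed", range(10))
    def test_shares_sum_to_one_hundred(self, seed):
        rng = np.random.default_rng(seed)
        totals = {f"g{i}": int(v) for i, v in enumerate(rng.integers(1, 500, 6))}
        assert sum(shares_from_totals(totals).values()) == pytest.approx(100.0, abs=0.02)

    def test_descriptive_shares_on_daily_table(self, six_season_features):
        out = descriptive_shares(six_season_features)
        assert sum(out["monthly_totals"].values()) == six_season_features["count"].sum()
        assert set(out["sanfu_shares"]) <= {"toufu", "zhongfu", "mofu", "non_sanfu"}
        assert sum(out["monthly_shares"].values()) == pytest.approx(100.0, abs=0.02)


class TestSplit:
    def test_split_by_year(self, six_season_features):
        train, valid = SplitSpec().split(six_season_features)
        assert set(train["year"].unique()) == {2014, 2015, 2016, 2017, 2018}
        assert set(valid["year"].unique()) == {2019}

    def test_missing_validation_year_is_an_error(self, six_season_features):
        spec = SplitSpec(frozenset({2014}), frozenset({2030}))
        with pytest.raises(ValueError, match="2030"):
            spec.split(six_season_features)

    def test_overlapping_years_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitSpec(frozenset({2014}), frozenset({2014}))


FEATURES = ["tmean_c", "tmax_c", "rh_pct", "heat_index_c", "dew_point_c", "day", "month"]


@pytest.fixture(scope="module")
def strong_signal_features() -> pd.DataFrame:
    """Six seasons with a strong exposure effect, so the heat drivers
    dominate any fitted predictor (log-RR 0.15 per degC above 28)."""
    from heatlag import met_features, synthetic

    surface = synthetic.TrueLagSurface.geometric(slope=0.15, threshold=28.0)
    cfg = synthetic.SyntheticConfig(seed=17, count_baseline=3.0, lag_effect=surface)
    daily = synthetic.generate_dataset(cfg)
    cal = synthetic.synthetic_sanfu_calendar(sorted(daily["year"].unique()))
    df = met_features.add_met_features(daily, calendar=cal)
    return df[df["burn_in"] == 0].copy()


@pytest.fixture(scope="module")
def report(six_season_features) -> EvalReport:
    usable = six_season_features[six_season_features["burn_in"] == 0]
    train, valid = SplitSpec().split(usable)
    return fit_predict_suite(train, valid, FEATURES, seed=0)


class TestSuite:
    def test_all_models_scored(self, report):
        assert {"regression_tree", "random_forest", "gbdt", "linear_svr", "arima"} <= set(
            report.metrics.index
        )
        np.testing.assert_allclose(
            report.metrics["rmse"] ** 2, report.metrics["mse"], atol=1e-9
        )

    def test_forest_beats_chance_on_strong_signal(self, strong_signal_features):
        train, valid = SplitSpec().split(strong_signal_features)
        strong = fit_predict_suite(train, valid, FEATURES, seed=0)
        assert strong.metrics.loc["random_forest", "r2"] > 0

    def test_single_tree_forest_equals_its_tree(self, six_season_features):
        usable = six_season_features[six_season_features["burn_in"] == 0]
        train, valid = SplitSpec().split(usable)
        rf = RFSpec(n_trees=1, seed=0).build()
        rf.fit(train[FEATURES], train["count"])
        np.testing.assert_allclose(
            rf.predict(valid[FEATURES]), rf.estimators_[0].predict(valid[FEATURES].to_numpy())
        )

    def test_rolling_arima_tracks_a_deterministic_trend(self):
        y = 1.0 + 0.5 * np.arange(160)
        preds = _rolling_arima(y[:100], y[100:], order=(0, 1, 0))
        errors = np.abs(preds - y[100:])
        assert np.all(errors[5:] < 0.05)

    def test_unknown_feature_rejected(self, six_season_features):
        usable = six_season_features[six_season_features["burn_in"] == 0]
        train, valid = SplitSpec().split(usable)
        with pytest.raises(ValueError, match="nope"):
            fit_predict_suite(train, valid, ["nope"])


class TestGridSearch:
    def test_one_point_grid(self):
        best, score = grid_search(lambda a: a, {"a": [3]}, score=lambda m: m)
        assert best == {"a": 3} and score == 3

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(lambda: None, {"a": []}, score=lambda m: 0)

    def test_tie_keeps_first_in_grid(self):
        best, _ = grid_search(lambda a: a, {"a": [1, 2]}, score=lambda m: 0.0)
        assert best == {"a": 1}

    def test_selects_true_polynomial_degree(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-2, 2, size=(600, 1))
        y = 1.0 + 2 * x[:, 0] - 1.5 * x[:, 0] ** 2 + rng.normal(0, 0.3, 600)
        xt, yt, xv, yv = x[:400], y[:400], x[400:], y[400:]

        def score(model):
            model.fit(xt, yt)
            return float(np.mean((model.predict(xv) - yv) ** 2))

        best, _ = grid_search(
            lambda degree: make_pipeline(PolynomialFeatures(degree), LinearRegression()),
            {"degree": [1, 2, 8]},
            score,
        )
        assert best == {"degree": 2}

    def test_deterministic_given_seeded_models(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(200, 3)), rng.normal(size=200)

        def score(model):
            model.fit(X[:150], y[:150])
            return float(np.mean((model.predict(X[150:]) - y[150:]) ** 2))

        runs = [
            grid_search(
                lambda max_depth: DecisionTreeRegressor(max_depth=max_depth, random_state=0),
                {"max_depth": [2, 3]},
                score,
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


@pytest.fixture(scope="module")
def fitted(six_season_features):
    usable = six_season_features[six_season_features["burn_in"] == 0]
    train, valid = SplitSpec().split(usable)
    rf = RFSpec(seed=0).build()
    rf.fit(train[FEATURES].to_numpy(), train["count"])
    return rf, valid


class TestSensitivity:
    def test_zero_perturbation_changes_nothing(self, fitted):
        rf, valid = fitted
        out = sensitivity_analysis(rf, valid, FEATURES, {f: 0.0 for f in FEATURES})
        np.testing.assert_allclose(out["rmse_change"], 0.0, atol=1e-12)

    def test_unused_feature_has_zero_delta(self):
        # a tree fitted on x0 alone never splits on x1
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x0": rng.normal(size=300), "x1": rng.normal(size=300)})
        df["count"] = 5 * df["x0"]
        tree = DecisionTreeRegressor(max_depth=3, random_state=0)
        tree.fit(df[["x0", "x1"]].to_numpy(), df["count"])
        assert 1 not in tree.tree_.feature  # x1 untouched
        out = sensitivity_analysis(tree, df, ["x0", "x1"], {"x1": 10.0})
        assert out.loc["x1", "rmse_change"] == 0.0

    def test_dominant_driver_moves_more_than_noise(self, strong_signal_features):
        rng = np.random.default_rng(4)
        df = strong_signal_features.copy()
        # noise on the same scale as the driver, so the comparison is fair
        df["pure_noise"] = rng.normal(0, df["heat_index_c"].std(), len(df))
        feats = ["heat_index_c", "pure_noise"]
        train, valid = SplitSpec().split(df)
        rf = RFSpec(seed=0).build()
        rf.fit(train[feats].to_numpy(), train["count"])
        out = sensitivity_analysis(rf, valid, feats, {"heat_index_c": 5.0, "pure_noise": 5.0})
        assert abs(out.loc["heat_index_c", "rmse_change"]) > abs(
            out.loc["pure_noise", "rmse_change"]
        )

    def test_unknown_feature_rejected(self, fitted):
        rf, valid = fitted
        with pytest.raises(ValueError, match="unknown"):
            sensitivity_analysis(rf, valid, FEATURES, {"bogus": 1.0})


def test_pearson_utility_matches_numpy(six_season_features):
    cols = ["tmean_c", "rh_pct", "count"]
    got = pearson_correlations(six_season_features, cols)
    expect = np.corrcoef(six_season_features[cols].to_numpy().T)
    np.testing.assert_allclose(got.to_numpy(), expect, atol=1e-12)
    assert got.loc["tmean_c", "rh_pct"] < 0  # hot days are drier by design
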