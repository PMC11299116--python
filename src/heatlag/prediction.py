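"""Count-prediction model suite, evaluation metrics and descriptives.

Trains the comparison suite — regression tree, random forest, gradient
boosting, linear SVR (all static multi-feature predictors) and ARIMA
(univariate, rolling one-step-ahead) — on a train/validation split by
calendar year, scores each with MSE, RMSE and R^2, and provides the
feature-perturbation sensitivity analysis and the descriptive share
statistics (monthly and sanfu-period percentages of total occurrences).

An LSTM slot exists as an optional plugin: pass a fitted-predictor factory
under the name 'lstm'; no neural-network dependency ships with the package.
"""

from __future__ import annotations

import decimal
import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "SplitSpec",
    "RFSpec",
    "EvalReport",
    "evaluate",
    "fit_predict_suite",
    "grid_search",
    "sensitivity_analysis",
    "descriptive_shares",
    "shares_from_totals",
    "pearson_correlations",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split by calendar year (default 2014-18 vs 2019)."""

    train_years: frozenset = frozenset({2014, 2015, 2016, 2017, 2018})
    validation_years: frozenset = frozenset({2019})

    def __post_init__(self) -> None:
        if not self.train_years or not self.validation_years:
            raise ValueError("both year sets must be non-empty")
        if set(self.train_years) & set(self.validation_years):
            raise ValueError("train and validation years must be disjoint")

    def split(self, df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        years = set(df["year"].unique())
        missing = set(self.validation_years) - years
        if missing:
            raise ValueError(f"validation years {sorted(missing)} absent from the data")
        return (
            df[df["year"].isin(self.train_years)].copy(),
            df[df["year"].isin(self.validation_years)].copy(),
        )


@dataclass(frozen=True)
class RFSpec:
    """The tuned random-forest configuration: 13 shallow trees.

    Depth 4, leaf size 1, split size 4 — the grid-search optimum of the
    motivating analysis; predictions are the plain average over the trees.
    """

    max_depth: int = 4
    min_samples_leaf: int = 1
    min_samples_split: int = 4
    n_trees: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_depth, self.min_samples_leaf, self.min_samples_split, self.n_trees) < 1:
            raise ValueError("all RFSpec sizes must be positive")

    def build(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            random_state=self.seed,
            n_jobs=1,
        )


def evaluate(y: Sequence[float], yhat: Sequence[float]) -> tuple[float, float, float]:
    """(MSE, RMSE, R2) of predictions against observations.

    MSE is the mean squared residual, RMSE its square root, and
    R2 = 1 - SS_res/SS_tot. A constant observation series leaves R2
    undefined (returned as nan with a warning), never silently 0.
    """
    ya = np.asarray(y, dtype=float)
    pa = np.asarray(yhat, dtype=float)
    if ya.shape != pa.shape or ya.ndim != 1 or len(ya) < 2:
        raise ValueError("evaluate requires two equal-length series of length >= 2")
    resid = ya - pa
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("R2 undefined: observations are constant", stacklevel=2)
        return mse, rmse, float("nan")
    return mse, rmse, 1.0 - float(np.sum(resid**2)) / ss_tot


@dataclass
class EvalReport:
    """Per-model validation metrics plus the prediction table."""

    metrics: pd.DataFrame  # index: model, columns: mse, rmse, r2
    predictions: pd.DataFrame  # date, observed, one column per model
    n_validation: int = 0

    def best_model(self) -> str:
        return str(self.metrics["rmse"].idxmin())


def _default_models(seed: int, rf_spec: RFSpec | None) -> dict:
    rf = rf_spec or RFSpec(seed=seed)
    return {
        "regression_tree": DecisionTreeRegressor(max_depth=4, random_state=seed),
        "random_forest": rf.build(),
        "gbdt": GradientBoostingRegressor(random_state=seed),
        "linear_svr": make_pipeline(StandardScaler(), LinearSVR(random_state=seed, max_iter=5000)),
    }


def _rolling_arima(
    train_y: np.ndarray, valid_y: np.ndarray, order: tuple = (2, 0, 1)
) -> np.ndarray:
    """One-step-ahead rolling ARIMA forecasts over the validation span.

    The model is fitted on the training series once, then the history is
    extended day by day (filter update, no refit) so each day's forecast
    uses all observations up to the previous day.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = SARIMAX(train_y, order=order, trend="c").fit(disp=0)
        preds = np.empty(len(valid_y))
        for i, obs in enumerate(valid_y):
            preds[i] = float(res.forecast(1)[0])
            res = res.append(np.asarray([obs]), refit=False)
    return preds


def fit_predict_suite(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    features: Sequence[str],
    target: str = "count",
    models: Mapping[str, object] | None = None,
    seed: int = 0,
    rf_spec: RFSpec | None = None,
    arima_order: tuple = (2, 0, 1),
) -> EvalReport:
    """Train the model suite and score it on the held-out season.

    Tabular models are trained once on the training years and statically
    predicted on the validation features; ARIMA ignores the features and
    rolls one-step-ahead through the validation counts. ``models`` may
    override/extend the suite with any fitted-predictor objects exposing
    fit/predict (an 'lstm' entry plugs in here).
    """
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise ValueError(f"features not in the table: {missing}")
    Xtr, ytr = train[list(features)].to_numpy(dtype=float), train[target].to_numpy(dtype=float)
    Xva, yva = validation[list(features)].to_numpy(dtype=float), validation[target].to_numpy(dtype=float)

    suite = dict(_default_models(seed, rf_spec))
    if models is not None:
        suite.update(models)

    preds = pd.DataFrame({"date": validation["date"].to_numpy(), "observed": yva})
    rows = {}
    for name, model in suite.items():
        if model is None:
            continue
        model.fit(Xtr, ytr)
        preds[name] = model.predict(Xva)
        rows[name] = evaluate(yva, preds[name].to_numpy())
    preds["arima"] = _rolling_arima(ytr, yva, order=arima_order)
    rows["arima"] = evaluate(yva, preds["arima"].to_numpy())

    metrics = pd.DataFrame.from_dict(rows, orient="index", columns=["mse", "rmse", "r2"])
    return EvalReport(metrics=metrics, predictions=preds, n_validation=len(yva))


def grid_search(
    build: Callable[..., object],
    grid: Mapping[str, Sequence],
    score: Callable[[object], float],
) -> tuple[dict, float]:
    """Exhaustive grid search; smaller score is better, ties keep grid order.

    ``build`` turns one parameter combination into a model object; ``score``
    evaluates it (e.g. validation MSE or a CV average).
    """
    keys = list(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    if not combos:
        raise ValueError("grid_search: empty grid")
    best, best_score = None, np.inf
    for combo in combos:
        params = dict(zip(keys, combo))
        s = float(score(build(**params)))
        if s < best_score:  # strict: first-in-grid wins ties
            best, best_score = params, s
    return best, best_score


def sensitivity_analysis(
    model,
    validation: pd.DataFrame,
    features: Sequence[str],
    deltas: Mapping[str, float],
    target: str = "count",
) -> pd.DataFrame:
    """Metric change when each feature is shifted by its delta, one at a time.

    Returns a table indexed by feature with the baseline and perturbed RMSE
    and their difference; unknown feature names are an error.
    """
    unknown = [f for f in deltas if f not in features]
    if unknown:
        raise ValueError(f"sensitivity_analysis: unknown features {unknown}")
    X = validation[list(features)].to_numpy(dtype=float)
    y = validation[target].to_numpy(dtype=float)
    base_mse, base_rmse, _ = evaluate(y, model.predict(X))
    rows = []
    for feat, delta in deltas.items():
        Xp = X.copy()
        Xp[:, list(features).index(feat)] += delta
        mse, rmse, _ = evaluate(y, model.predict(Xp))
        rows.append(
            {
                "feature": feat,
                "delta": delta,
                "baseline_rmse": base_rmse,
                "perturbed_rmse": rmse,
                "rmse_change": rmse - base_rmse,
                "mse_change": mse - base_mse,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _round_half_up(x: float, places: int = 2) -> float:
    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("1." + "0" * places), rounding=decimal.ROUND_HALF_UP
        )
    )


def shares_from_totals(totals: Mapping[str, float]) -> dict:
    """Percentage share of each group total, round-half-up to 2 decimals."""
    overall = float(sum(totals.values()))
    if overall == 0:
        raise ZeroDivisionError("shares undefined: overall total is zero")
    return {k: _round_half_up(100.0 * v / overall) for k, v in totals.items()}


def descriptive_shares(daily: pd.DataFrame) -> dict:
    """Monthly and sanfu-period occurrence totals and percentage shares.

    Expects columns count and month, and optionally the toufu/zhongfu/mofu
    indicators; days with no sanfu flag count as non-sanfu.
    """
    monthly_totals = daily.groupby("month")["count"].sum().to_dict()
    out = {
        "monthly_totals": {int(k): int(v) for k, v in monthly_totals.items()},
        "monthly_shares": shares_from_totals(monthly_totals),
    }
    if {"toufu", "zhongfu", "mofu"}.issubset(daily.columns):
        period = np.select(
            [daily["toufu"] == 1, daily["zhongfu"] == 1, daily["mofu"] == 1],
            ["toufu", "zhongfu", "mofu"],
            default="non_sanfu",
        )
        totals = daily.groupby(period)["count"].sum().to_dict()
        out["sanfu_totals"] = {k: int(v) for k, v in totals.items()}
        out["sanfu_shares"] = shares_from_totals(totals)
    return out


def pearson_correlations(df: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Plain Pearson correlation matrix of the named (or all numeric) columns."""
    sub = df[list(columns)] if columns is not None else df.select_dtypes("number")
    return sub.corr(method="pearson")
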