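"""Reference values from the motivating heatstroke surveillance study.

These are benchmark numbers reported for the original six-season
(2014-2019, May-September) urban surveillance dataset, which is not
redistributable here. They serve two purposes only: as inputs to the
descriptive-share computation (the printed monthly and sanfu-period
occurrence totals) and as an internal-consistency check on the published
evaluation metrics (sqrt(MSE) must agree with the printed RMSE up to
rounding). They are documentation of the original analysis, never training
data or test expectations for the synthetic pipeline.
"""

from __future__ import annotations

#: Heatstroke occurrences per month, May..September, 2014-2019 pooled.
MONTHLY_COUNTS = {"may": 24, "june": 178, "july": 1753, "august": 966, "september": 43}

#: Heatstroke occurrences by sanfu period over the same span.
SANFU_COUNTS = {"toufu": 488, "zhongfu": 1630, "mofu": 227, "non_sanfu": 619}

#: Published validation metrics (MSE, RMSE, R2) of the six model families.
MODEL_METRICS = {
    "regression_tree": (15.13, 3.89, 0.79),
    "random_forest": (12.74, 3.57, 0.82),
    "gbdt": (14.64, 3.82, 0.80),
    "linear_svr": (14.86, 3.85, 0.80),
    "arima": (34.58, 5.89, 0.52),
    "lstm": (44.86, 6.70, 0.38),
}

#: Feature set selected by Boruta on the original data (documentation only;
#: reproducing it requires the original dataset).
SELECTED_FEATURES = (
    "day",
    "tmax_c",
    "tmean_c",
    "rh_pct",
    "zhongfu",
    "is_heatwave",
    "heat_index_c",
    "dew_point_c",
)
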