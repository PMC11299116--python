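# Demo pipeline configuration: synthetic six-season run.
# `heatlag all --config examples/config.yaml --out-dir results`
seed: 20140501

synthetic:
  years: [2014, 2015, 2016, 2017, 2018, 2019]
  # lag_effect defaults to the heat-index surface: threshold 30 degC,
  # log-RR slope 0.05 per degC, weights decaying over lags 0-5

split:
  train_years: [2014, 2015, 2016, 2017, 2018]
  validation_years: [2019]

exposure: heat_index_c
exposure_basis: {kind: ns, df: 4}
lag_basis: {max_lag: 30, degree: 4}
seasonal_df: 10

boruta:
  max_iter: 50

random_forest:
  max_depth: 4
  min_samples_leaf: 1
  min_samples_split: 4
  n_trees: 13

warning_rules:
  hi_threshold: 30.0
  td_threshold: 23.0
  tmax_threshold: 35.0
  reinforced_days: 5
  rh_low_cut: 65.0
  rh_high_cut: 85.0
  rh_low_window: [20, 25]
  rh_high_window: [22, 28]
  # count_threshold omitted: defaults to the 90th percentile of training counts

# A real-data run must supply the true lunar-calendar dates, e.g.:
# sanfu_calendar:
#   2019:
#     toufu: ["2019-07-12", "2019-07-21"]
#     zhongfu: ["2019-07-22", "2019-08-10"]
#     mofu: ["2019-08-11", "2019-08-20"]
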