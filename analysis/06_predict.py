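#!/usr/bin/env python
"""Train and compare the count-prediction model suite.

2014-2018 seasons train, 2019 validates. Tabular models (regression tree,
the 13-tree random forest, gradient boosting, linear SVR) predict statically
from the selected features; ARIMA rolls one-step-ahead through 2019. Also
runs the feature-perturbation sensitivity analysis on the random forest.
Writes results/eval_report.csv, predictions.csv and sensitivity.csv.
"""

import json
from pathlib import Path

from heatlag import io
from heatlag.prediction import RFSpec, SplitSpec, fit_predict_suite, sensitivity_analysis

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    feats = io.read_daily_csv(OUT / "features.csv", require_count=True)
    usable = feats[feats["burn_in"] == 0]
    sel = json.loads((OUT / "selected_features.json").read_text())
    # confirmed features if any; undecided (tentative) features are retained
    # rather than dropped, as usual for all-relevant selection
    selected = sel["confirmed"] + sel["tentative"]
    train, valid = SplitSpec().split(usable)
    report = fit_predict_suite(train, valid, selected, seed=20140501)
    report.metrics.to_csv(OUT / "eval_report.csv")
    report.predictions.to_csv(OUT / "predictions.csv", index=False)

    rf = RFSpec(seed=20140501).build()
    rf.fit(train[selected].to_numpy(), train["count"].to_numpy())
    sens = sensitivity_analysis(rf, valid, selected, {f: 5.0 for f in selected})
    sens.to_csv(OUT / "sensitivity.csv")

    print(f"features used: {selected}")
    print(report.metrics.round(3).to_string())
    print(f"best model by RMSE: {report.best_model()}")
    print("sensitivity (RMSE change per +5-unit shift):")
    print(sens["rmse_change"].round(3).to_string())
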