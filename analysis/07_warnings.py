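#!/usr/bin/env python
"""Issue the rule-based early-warning schedule for the validation season.

Applies the composite warning mechanism to the random-forest predictions
for 2019: count-threshold warnings, 5-day reinforcement when a thermal
driver (heat index > 30, dew point > 23, Tmax > 35 degC) co-occurs, and the
delayed humidity windows (RH < 65% -> d+20..d+25; RH > 85% -> d+22..d+28).
The count threshold defaults to the 90th percentile of training counts.
Writes results/warnings.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from heatlag import io
from heatlag.warning_engine import WarningRules, generate_warnings

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    feats = io.read_daily_csv(OUT / "features.csv", require_count=True)
    preds = pd.read_csv(OUT / "predictions.csv", parse_dates=["date"])
    threshold = float(np.percentile(feats.loc[feats["year"] < 2019, "count"], 90))
    rules = WarningRules(count_threshold=threshold)

    series = pd.Series(preds["random_forest"].to_numpy(), index=pd.DatetimeIndex(preds["date"]))
    drivers = feats.set_index(pd.DatetimeIndex(feats["date"])).loc[
        series.index, ["heat_index_c", "dew_point_c", "tmax_c", "rh_pct"]
    ]
    schedule = generate_warnings(series, drivers, rules)
    frame = schedule.to_frame()
    frame.to_csv(OUT / "warnings.csv", index=False)

    print(f"count threshold (90th pct of training counts): {threshold:.1f}")
    print(f"warned days: {len(frame)} of {len(series)} "
          f"({(frame['level'] == 'reinforced').sum()} reinforced)")
    print(frame.head(8).to_string(index=False))
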