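#!/usr/bin/env python
"""Derive the meteorological and calendar feature set.

Joins heat index, dew point, CMA heatwave flags, sanfu indicators (the
schematic synthetic calendar) and weekday/holiday features onto the daily
table from 01_simulate.py; writes results/features.csv.
"""

from pathlib import Path

from heatlag import io, met_features
from heatlag.synthetic import synthetic_sanfu_calendar

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    daily = io.read_daily_csv(OUT / "daily.csv", require_count=True)
    calendar = synthetic_sanfu_calendar(sorted(daily["year"].unique()))
    feats = met_features.add_met_features(daily, calendar=calendar)
    path = io.write_daily_csv(feats, OUT / "features.csv")
    print(f"wrote {path} with columns: {', '.join(feats.columns)}")
    print(f"heatwave days: {int(feats['is_heatwave'].sum())}")
    print(f"mean heat index {feats['heat_index_c'].mean():.1f} degC, "
          f"mean dew point {feats['dew_point_c'].mean():.1f} degC")
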