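"""Rule-based heat-health early-warning engine.

Turns daily predicted heatstroke counts and the driver indicators (heat
index, dew point, daily maximum temperature, relative humidity) into a
dated warning schedule:

1. predicted count above the count threshold -> *warning* that day;
2. if, in addition, any thermal driver exceeds its threshold (heat index
   > 30 degC, dew point > 23 degC, or Tmax > 35 degC) -> *reinforced*
   warnings for that day and the following four (at least five consecutive
   days in total);
3. relative humidity below 65% on day d -> warnings on days d+20..d+25;
4. relative humidity above 85% on day d -> warnings on days d+22..d+28.

The low-humidity and high-humidity delayed rules fire independently of the
count trigger (the medium 65-78% humidity band acts through the same-day
reinforcement, not through a delayed window). Overlapping directives merge
to the highest level, and every emitted entry records the rules and origin
dates that produced it; delayed warnings beyond the data horizon are
emitted as future-dated entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WarningRules", "WarningSchedule", "generate_warnings", "merge_schedules"]

_LEVELS = {"none": 0, "warning": 1, "reinforced": 2}


@dataclass(frozen=True)
class WarningRules:
    """Thresholds and windows of the composite warning mechanism.

    count_threshold has no universal value; a data-adaptive default (the
    90th percentile of training-period counts) is supplied by the pipeline
    and recorded in the run log. Both delayed windows are inclusive.
    """

    count_threshold: float = 5.0
    hi_threshold: float = 30.0  # degC heat index
    td_threshold: float = 23.0  # degC dew point
    tmax_threshold: float = 35.0  # degC daily maximum
    reinforced_days: int = 5
    rh_low_cut: float = 65.0  # %
    rh_high_cut: float = 85.0  # %
    rh_low_window: tuple = (20, 25)  # days after a dry day, inclusive
    rh_high_window: tuple = (22, 28)  # days after a humid day, inclusive

    def __post_init__(self) -> None:
        for win in (self.rh_low_window, self.rh_high_window):
            if not (0 < win[0] <= win[1]):
                raise ValueError(f"delayed-warning window {win} must be ordered and positive")
        if self.reinforced_days < 1:
            raise ValueError("reinforced_days must be >= 1")
        for name in ("count_threshold", "hi_threshold", "td_threshold", "tmax_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class WarningSchedule:
    """Per-date warning levels with full rule provenance.

    ``entries`` maps each warned date to a dict with the level and the list
    of (rule, origin_date) pairs that triggered it.
    """

    entries: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "date": d,
                "level": e["level"],
                "rules": ";".join(sorted({r for r, _ in e["sources"]})),
                "origins": ";".join(sorted({str(o.date()) for _, o in e["sources"]})),
            }
            for d, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["date", "level", "rules", "origins"])

    def level(self, date) -> str:
        e = self.entries.get(pd.Timestamp(date))
        return e["level"] if e else "none"

    def dates(self, level: str | None = None) -> list:
        return sorted(
            d for d, e in self.entries.items() if level is None or e["level"] == level
        )


def _add(entries: dict, date: pd.Timestamp, level: str, rule: str, origin: pd.Timestamp) -> None:
    e = entries.setdefault(date, {"level": "none", "sources": []})
    if _LEVELS[level] > _LEVELS[e["level"]]:
        e["level"] = level
    e["sources"].append((rule, origin))


def generate_warnings(
    predictions: pd.Series,
    features: pd.DataFrame,
    rules: WarningRules = WarningRules(),
) -> WarningSchedule:
    """Apply the warning rules to aligned predictions and driver features.

    ``predictions`` is a date-indexed series of predicted daily counts;
    ``features`` a date-indexed frame with columns heat_index_c,
    dew_point_c, tmax_c, rh_pct. Indices must match exactly.
    """
    pred = predictions.copy()
    pred.index = pd.DatetimeIndex(pred.index)
    feats = features.copy()
    feats.index = pd.DatetimeIndex(feats.index)
    mismatch = pred.index.symmetric_difference(feats.index)
    if len(mismatch):
        raise ValueError(
            f"predictions and features are misaligned on dates {[str(d.date()) for d in mismatch[:10]]}"
        )

    entries: dict = {}
    one_day = pd.Timedelta(days=1)
    for d in pred.index:
        if pred.loc[d] > rules.count_threshold:
            _add(entries, d, "warning", "count", d)
            hot = (
                feats.loc[d, "heat_index_c"] > rules.hi_threshold
                or feats.loc[d, "dew_point_c"] > rules.td_threshold
                or feats.loc[d, "tmax_c"] > rules.tmax_threshold
            )
            if hot:
                for k in range(rules.reinforced_days):
                    _add(entries, d + k * one_day, "reinforced", "count+driver", d)
        rh = feats.loc[d, "rh_pct"]
        if rh < rules.rh_low_cut:
            lo, hi = rules.rh_low_window
            for k in range(lo, hi + 1):
                _add(entries, d + k * one_day, "warning", "rh_low", d)
        elif rh > rules.rh_high_cut:
            lo, hi = rules.rh_high_window
            for k in range(lo, hi + 1):
                _add(entries, d + k * one_day, "warning", "rh_high", d)
    return WarningSchedule(entries)


def merge_schedules(*schedules: WarningSchedule) -> WarningSchedule:
    """Union of schedules; each date keeps the highest level, provenance pooled."""
    merged: dict = {}
    for s in schedules:
        for d, e in s.entries.items():
            for rule, origin in e["sources"]:
                _add(merged, d, "none", rule, origin)
            m = merged[d]
            if _LEVELS[e["level"]] > _LEVELS[m["level"]]:
                m["level"] = e["level"]
    # de-duplicate provenance so self-merge is exactly idempotent
    for e in merged.values():
        e["sources"] = sorted(set(e["sources"]))
    return WarningSchedule(merged)
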