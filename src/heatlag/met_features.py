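"""Derived meteorological and calendar features.

Computes the apparent-temperature ("heat index") and dew-point indicators
that combine air temperature with relative humidity, detects
high-temperature heatwaves under the China Meteorological Administration
rule, and encodes the traditional *sanfu* hot-period calendar together with
weekday/holiday indicators.

All public temperature interfaces are in degrees Celsius; the heat-index
regression is evaluated internally on the Fahrenheit scale, where its
coefficients are native.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MagnusParams",
    "HeatIndexCoefficients",
    "SanfuCalendar",
    "dew_point",
    "heat_index",
    "detect_heatwaves",
    "encode_sanfu",
    "calendar_features",
    "add_met_features",
]


@dataclass(frozen=True)
class MagnusParams:
    """Magnus saturation-vapour-pressure constants.

    ``a`` is dimensionless, ``b`` is in degrees Celsius. The defaults are the
    widely used Magnus coefficients for water over the meteorological range.
    """

    a: float = 17.27
    b: float = 237.7

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Magnus parameters a and b must be positive")


#: Rothfusz regression coefficients (degrees Fahrenheit), the standard NOAA/NWS
#: realisation of the 9-term apparent-temperature polynomial
#: HI = c1 + c2*T + c3*RH + c4*T*RH + c5*T^2 + c6*RH^2
#:      + c7*T^2*RH + c8*T*RH^2 + c9*T^2*RH^2.
_ROTHFUSZ_F = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


@dataclass(frozen=True)
class HeatIndexCoefficients:
    """The 9 coefficients of the heat-index polynomial plus its valid range.

    ``coefficients`` are on the Fahrenheit scale by default (Rothfusz);
    ``valid_range_f`` is the temperature (deg F) above which the full
    regression applies — below it a simple near-linear formula is used.
    """

    coefficients: tuple = _ROTHFUSZ_F
    valid_range_f: float = 80.0

    def __post_init__(self) -> None:
        if len(self.coefficients) != 9:
            raise ValueError("heat index requires exactly 9 coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("heat index coefficients must be finite")


def _c_to_f(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def _f_to_c(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def dew_point(t, rh, params: MagnusParams = MagnusParams()):
    """Dew-point temperature (deg C) via the Magnus approximation.

    Td = b*gamma / (a - gamma) with gamma(T, RH) = a*T/(b+T) + ln(RH/100).

    Parameters
    ----------
    t : scalar or array-like
        Air temperature in degrees Celsius; must exceed ``-b``.
    rh : scalar or array-like
        Relative humidity in percent, in (0, 100].
    """
    t_arr = np.asarray(t, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(~np.isfinite(rh_arr)):
        raise ValueError("dew_point: inputs must be finite")
    if np.any(rh_arr <= 0) or np.any(rh_arr > 100):
        raise ValueError("dew_point: relative humidity must lie in (0, 100] %")
    if np.any(t_arr <= -params.b):
        raise ValueError(f"dew_point: temperature must exceed {-params.b} degC")
    gamma = params.a * t_arr / (params.b + t_arr) + np.log(rh_arr / 100.0)
    td = params.b * gamma / (params.a - gamma)
    return td if td.ndim else float(td)


def heat_index(t, rh, coeffs: HeatIndexCoefficients = HeatIndexCoefficients()):
    """Apparent temperature (deg C) combining air temperature and humidity.

    Follows the NWS algorithm: a simple near-linear formula at mild
    temperatures, switching to the 9-coefficient Rothfusz regression (with
    the published low-RH and high-RH adjustments) once the simple value
    reaches the regression's validity range (80 deg F).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    rh_arr = np.atleast_1d(np.asarray(rh, dtype=float))
    if np.any(~np.isfinite(t_arr)) or np.any(~np.isfinite(rh_arr)):
        raise ValueError("heat_index: inputs must be finite")
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise ValueError("heat_index: relative humidity must lie in [0, 100] %")
    t_arr, rh_arr = np.broadcast_arrays(t_arr, rh_arr)

    tf = _c_to_f(t_arr)
    # simple formula (the NWS "Steadman" approximation averaged with T)
    simple = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + rh_arr * 0.094)
    hi_f = simple.copy()

    full = simple >= coeffs.valid_range_f
    if np.any(full):
        c1, c2, c3, c4, c5, c6, c7, c8, c9 = coeffs.coefficients
        T, R = tf[full], rh_arr[full]
        reg = (
            c1 + c2 * T + c3 * R + c4 * T * R + c5 * T * T + c6 * R * R
            + c7 * T * T * R + c8 * T * R * R + c9 * T * T * R * R
        )
        low_rh = (R < 13) & (T >= 80) & (T <= 112)
        reg = np.where(
            low_rh,
            reg - ((13 - R) / 4) * np.sqrt(np.clip(17 - np.abs(T - 95), 0, None) / 17),
            reg,
        )
        high_rh = (R > 85) & (T >= 80) & (T <= 87)
        reg = np.where(high_rh, reg + ((R - 85) / 10) * ((87 - T) / 5), reg)
        hi_f[full] = reg

    out = _f_to_c(hi_f)
    return out if np.asarray(t).ndim else float(out[0])


def detect_heatwaves(
    dates: Sequence, tmax: Sequence[float], threshold_c: float = 35.0, min_run: int = 3
) -> pd.Series:
    """Flag days belonging to a high-temperature heatwave.

    A heatwave is a maximal run of at least ``min_run`` *consecutive calendar
    days* whose daily maximum temperature meets ``threshold_c`` (CMA rule:
    >= 35 deg C on >= 3 consecutive days). A gap in the date sequence breaks
    a run, so May-September seasons in different years never join.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique()
        raise ValueError(f"detect_heatwaves: duplicate dates {list(dup.date)}")
    if not idx.is_monotonic_increasing:
        raise ValueError("detect_heatwaves: dates must be strictly increasing")
    tm = np.asarray(tmax, dtype=float)
    if len(tm) != len(idx):
        raise ValueError("detect_heatwaves: dates and tmax lengths differ")

    hot = tm >= threshold_c
    day_gap = np.diff(idx.values).astype("timedelta64[D]").astype(int)
    flags = np.zeros(len(tm), dtype=int)
    start = 0
    for i in range(1, len(tm) + 1):
        # close a candidate segment at a calendar gap, a cool day, or the end
        boundary = i == len(tm) or not hot[i] or (hot[i] and day_gap[i - 1] != 1)
        if not hot[start]:
            start = i
            continue
        if i == len(tm) or not hot[i] or day_gap[i - 1] != 1:
            if i - start >= min_run:
                flags[start:i] = 1
            start = i
    return pd.Series(flags, index=idx, name="is_heatwave")


@dataclass
class SanfuCalendar:
    """Per-year dates of the three *sanfu* periods.

    *Sanfu* is the traditional Chinese hottest-period calendar: *toufu*
    (opening, exactly 10 days), *zhongfu* (middle, 10 or 20 days) and *mofu*
    (closing, exactly 10 days), consecutive non-overlapping intervals in
    July-August. Dates vary by year and must be supplied; validation happens
    on construction.
    """

    periods: Mapping[int, Mapping[str, tuple]] = field(default_factory=dict)

    PERIOD_NAMES = ("toufu", "zhongfu", "mofu")

    def __post_init__(self) -> None:
        norm: dict[int, dict[str, tuple[_dt.date, _dt.date]]] = {}
        for year, spans in self.periods.items():
            year = int(year)
            missing = [p for p in self.PERIOD_NAMES if p not in spans]
            if missing:
                raise ValueError(f"sanfu calendar {year}: missing periods {missing}")
            parsed = {}
            for name in self.PERIOD_NAMES:
                start, end = spans[name]
                start = pd.Timestamp(start).date()
                end = pd.Timestamp(end).date()
                ndays = (end - start).days + 1
                if name in ("toufu", "mofu") and ndays != 10:
                    raise ValueError(
                        f"sanfu calendar {year}: {name} spans {ndays} days, must be 10"
                    )
                if name == "zhongfu" and ndays not in (10, 20):
                    raise ValueError(
                        f"sanfu calendar {year}: zhongfu spans {ndays} days, must be 10 or 20"
                    )
                parsed[name] = (start, end)
            if not (
                parsed["toufu"][1] < parsed["zhongfu"][0]
                and parsed["zhongfu"][1] < parsed["mofu"][0]
            ):
                raise ValueError(f"sanfu calendar {year}: periods must be ordered and disjoint")
            norm[year] = parsed
        self.periods = norm

    @classmethod
    def from_dict(cls, d: Mapping) -> "SanfuCalendar":
        return cls(periods=d)

    def years(self) -> list[int]:
        return sorted(self.periods)


def encode_sanfu(dates: Sequence, calendar: SanfuCalendar) -> pd.DataFrame:
    """Binary toufu/zhongfu/mofu indicators for each date.

    Each flag is 1 iff the date lies in the closed interval of that period in
    its year's calendar; the three periods are disjoint so at most one flag
    is set. Every year appearing in ``dates`` must be configured.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    missing = sorted(set(idx.year) - set(calendar.periods))
    if missing:
        raise ValueError(f"encode_sanfu: no sanfu dates configured for years {missing}")
    out = pd.DataFrame(0, index=idx, columns=list(SanfuCalendar.PERIOD_NAMES), dtype=int)
    for ts in idx:
        spans = calendar.periods[ts.year]
        d = ts.date()
        for name, (start, end) in spans.items():
            if start <= d <= end:
                out.loc[ts, name] = 1
    return out


def calendar_features(dates: Sequence, holidays: Iterable = ()) -> pd.DataFrame:
    """Weekday index (Monday=0), holiday flag and year/month/day columns."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    holiday_set = {pd.Timestamp(h).date() for h in holidays}
    return pd.DataFrame(
        {
            "year": idx.year,
            "month": idx.month,
            "day": idx.day,
            "weekday": idx.weekday,
            "holiday": [int(ts.date() in holiday_set) for ts in idx],
        },
        index=idx,
    )


def add_met_features(
    daily: pd.DataFrame,
    calendar: SanfuCalendar | None = None,
    holidays: Iterable = (),
) -> pd.DataFrame:
    """Join all derived features onto a daily table.

    Expects columns ``date``, ``tmean_c``, ``tmax_c``, ``rh_pct``; returns a
    copy with heat_index_c, dew_point_c, is_heatwave, calendar columns and
    (if a calendar is given) the sanfu indicators.
    """
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    df["heat_index_c"] = heat_index(df["tmean_c"].to_numpy(), df["rh_pct"].to_numpy())
    df["dew_point_c"] = dew_point(df["tmean_c"].to_numpy(), df["rh_pct"].to_numpy())
    df["is_heatwave"] = detect_heatwaves(dates, df["tmax_c"].to_numpy()).to_numpy()
    cal = calendar_features(dates, holidays)
    for col in cal.columns:
        df[col] = cal[col].to_numpy()
    if calendar is not None:
        sf = encode_sanfu(dates, calendar)
        for col in sf.columns:
            df[col] = sf[col].to_numpy()
    return df
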