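"""Synthetic warm-season weather and heatstroke-count generator.

Emulates multi-year May-September daily surveillance series: a seasonal
sinusoid plus AR(1) noise for daily mean temperature, a positive offset for
the daily maximum, relative humidity anti-correlated with temperature, and
Poisson counts driven by a *known* distributed-lag exposure-response
surface. Because the generative surface is known in closed form, every
downstream stage (feature engineering, DLNM fitting, feature selection,
prediction, warning rules) can be validated against ground truth.

The generative count model is threshold-linear on the log scale:

    log mu_t = log(baseline) + slope * sum_l w_l * max(0, x_{t-l} - threshold)

with non-negative lag weights w_l summing to one, so the cumulative relative
risk of holding the exposure at x versus the threshold is exactly
exp(slope * (x - threshold)). A hook accepts arbitrary user rate functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import met_features

__all__ = [
    "TrueLagSurface",
    "SyntheticConfig",
    "generate_weather",
    "generate_counts",
    "generate_dataset",
    "synthetic_sanfu_calendar",
]

_EXPOSURES = ("tmean", "tmax", "rh", "heat_index", "dew_point")


@dataclass(frozen=True)
class TrueLagSurface:
    """Known exposure-lag-response surface of the generator.

    slope is the log-relative-risk per exposure unit above threshold;
    lag_weights distribute that effect over lags 0..L and must be
    non-negative, finite and sum to 1.
    """

    exposure_name: str = "heat_index"
    threshold: float = 30.0
    slope: float = 0.05
    lag_weights: tuple = (0.35, 0.25, 0.17, 0.11, 0.07, 0.05)

    def __post_init__(self) -> None:
        if self.exposure_name not in _EXPOSURES:
            raise ValueError(f"exposure_name must be one of {_EXPOSURES}")
        w = np.asarray(self.lag_weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("lag_weights must be finite and non-negative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("lag_weights must sum to 1")

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1

    def cumulative_rr(self, x: float) -> float:
        """Closed-form cumulative RR of exposure x versus the threshold."""
        return float(np.exp(self.slope * max(0.0, x - self.threshold)))

    @staticmethod
    def geometric(
        exposure_name: str = "heat_index",
        threshold: float = 30.0,
        slope: float = 0.05,
        max_lag: int = 5,
        decay: float = 0.6,
    ) -> "TrueLagSurface":
        """Geometric-decay lag weights over lags 0..max_lag, normalised."""
        w = decay ** np.arange(max_lag + 1)
        return TrueLagSurface(exposure_name, threshold, slope, tuple(w / w.sum()))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    The defaults emulate a six-season (2014-2019) May-September series from
    a hot-humid southern-Chinese city: daily mean temperature following the
    annual sinusoid (base 24 °C, half-swing 5 °C, peak in late July, so the
    in-season range is about 19-31 °C before noise), day-to-day AR(1)
    noise, humidity around 75% falling ~1.5 points per degree of warmth,
    and a baseline of about two heatstroke cases per day away from heat
    extremes.
    """

    years: tuple = (2014, 2015, 2016, 2017, 2018, 2019)
    season_span: tuple = ("05-01", "09-30")
    temp_base: float = 24.0  # annual mean level of the sinusoid, degC
    temp_amplitude: float = 5.0  # annual half peak-to-trough swing, degC
    temp_peak_doy: int = 205  # day-of-year of the sinusoid peak (~Jul 24)
    temp_noise_sd: float = 1.5  # degC, innovation sd of the AR(1) noise
    temp_ar_coef: float = 0.6  # AR(1) coefficient, in (-1, 1)
    tmax_offset_mean: float = 5.5  # degC mean Tmean->Tmax offset
    tmax_offset_sd: float = 1.5  # degC, half-normal spread of the offset
    rh_base: float = 75.0  # %, humidity at the seasonal mean temperature
    rh_temp_coupling: float = -1.5  # % per degC (negative: hot days are drier)
    rh_noise_sd: float = 8.0  # %
    count_baseline: float = 2.0  # expected daily cases at reference conditions
    lag_effect: TrueLagSurface = field(default_factory=TrueLagSurface)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("years must be non-empty")
        if self.seed is None:
            raise ValueError("a seed is mandatory: the generator is fully reproducible")
        if not (-1 < self.temp_ar_coef < 1):
            raise ValueError("temp_ar_coef must lie in (-1, 1)")
        if self.count_baseline <= 0:
            raise ValueError("count_baseline must be positive")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _season_dates(years: Sequence[int], span: tuple) -> pd.DatetimeIndex:
    start_md, end_md = span
    chunks = [
        pd.date_range(f"{y}-{start_md}", f"{y}-{end_md}", freq="D") for y in sorted(years)
    ]
    return pd.DatetimeIndex(np.concatenate([c.values for c in chunks]))


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the daily weather table (no counts yet).

    One row per in-season date with columns date, year, tmean_c, tmax_c,
    rh_pct. Tmean is the seasonal sinusoid plus AR(1) noise (noise restarts
    each season: seasons are separated by seven winter months); Tmax adds a
    positive half-normal offset; RH couples linearly to the Tmean anomaly
    plus Gaussian noise, clipped to [5, 100].
    """
    rng = np.random.default_rng(config.seed)
    dates = _season_dates(config.years, config.season_span)
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = config.temp_base + config.temp_amplitude * np.cos(
        2 * np.pi * (doy - config.temp_peak_doy) / 365.25
    )

    years_arr = dates.year.to_numpy()
    noise = np.empty(len(dates))
    rho, sd = config.temp_ar_coef, config.temp_noise_sd
    stat_sd = sd / np.sqrt(1 - rho**2) if sd > 0 else 0.0
    for i in range(len(dates)):
        new_block = i == 0 or years_arr[i] != years_arr[i - 1]
        if sd == 0:
            noise[i] = 0.0
        elif new_block:
            noise[i] = rng.normal(0.0, stat_sd)  # start at stationarity
        else:
            noise[i] = rho * noise[i - 1] + rng.normal(0.0, sd)
    tmean = seasonal + noise

    offset = np.abs(rng.normal(0.0, config.tmax_offset_sd, len(dates)))
    tmax = tmean + config.tmax_offset_mean + offset - config.tmax_offset_sd * np.sqrt(2 / np.pi)
    tmax = np.maximum(tmax, tmean)  # Tmax never below Tmean

    rh = (
        config.rh_base
        + config.rh_temp_coupling * (tmean - config.temp_base)
        + rng.normal(0.0, config.rh_noise_sd, len(dates))
    )
    rh = np.clip(rh, 5.0, 100.0)

    return pd.DataFrame(
        {
            "date": dates,
            "year": years_arr,
            "tmean_c": tmean,
            "tmax_c": tmax,
            "rh_pct": rh,
        }
    )


def _exposure_column(weather: pd.DataFrame, name: str) -> np.ndarray:
    if name == "tmean":
        return weather["tmean_c"].to_numpy(dtype=float)
    if name == "tmax":
        return weather["tmax_c"].to_numpy(dtype=float)
    if name == "rh":
        return weather["rh_pct"].to_numpy(dtype=float)
    if name == "heat_index":
        return np.asarray(
            met_features.heat_index(weather["tmean_c"].to_numpy(), weather["rh_pct"].to_numpy())
        )
    if name == "dew_point":
        return np.asarray(
            met_features.dew_point(weather["tmean_c"].to_numpy(), weather["rh_pct"].to_numpy())
        )
    raise ValueError(f"unknown exposure {name!r}")


def generate_counts(
    weather: pd.DataFrame,
    surface: TrueLagSurface,
    baseline: float,
    seed: int,
    rate_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Add Poisson heatstroke counts driven by the lag surface.

    log mu_t = log(baseline) + slope * sum_l w_l * max(0, x_{t-l} - threshold),
    with lags taken within each season (block = year); the first L days of
    each season carry burn_in = 1 and should be excluded from fitting.

    ``rate_fn`` optionally replaces the threshold-linear log-rate increment:
    it receives the exposure series and must return the per-day log-rate
    increment before lag-weighting. ``dispersion`` switches to negative
    binomial draws with that gamma heterogeneity (var = mu + mu^2/dispersion).
    """
    L = surface.max_lag
    year = weather["year"].to_numpy()
    if np.min(np.bincount(pd.factorize(year)[0])) <= L:
        raise ValueError(f"each season needs more than max_lag={L} days to burn in lags")
    x = _exposure_column(weather, surface.exposure_name)
    if rate_fn is None:
        incr = surface.slope * np.maximum(0.0, x - surface.threshold)
    else:
        incr = np.asarray(rate_fn(x), dtype=float)

    w = np.asarray(surface.lag_weights, dtype=float)
    n = len(x)
    lag_sum = np.full(n, np.nan)
    burn = np.ones(n, dtype=int)
    pos = 0
    for i in range(n):
        pos = 0 if i == 0 or year[i] != year[i - 1] else pos + 1
        if pos >= L:
            lag_sum[i] = float(np.dot(w, incr[i - np.arange(L + 1)]))
            burn[i] = 0

    log_mu = np.log(baseline) + np.where(burn == 1, 0.0, lag_sum)
    mu = np.exp(log_mu)
    bad = ~np.isfinite(mu)
    if np.any(bad):
        first = weather["date"].iloc[int(np.argmax(bad))]
        raise ArithmeticError(f"non-finite Poisson rate generated on {first}")

    rng = np.random.default_rng(seed)
    if dispersion is None:
        counts = rng.poisson(mu)
    else:
        counts = rng.poisson(mu * rng.gamma(dispersion, 1.0 / dispersion, n))

    out = weather.copy()
    out["count"] = counts.astype(int)
    out["burn_in"] = burn
    return out


def synthetic_sanfu_calendar(years: Sequence[int]) -> "met_features.SanfuCalendar":
    """A schematic sanfu calendar for synthetic data (NOT historical dates).

    Every year gets toufu Jul 11-20, zhongfu Jul 21 - Aug 9 (20 days) and
    mofu Aug 10-19. Real analyses must supply the true lunar-calendar dates
    via configuration.
    """
    periods = {
        int(y): {
            "toufu": (f"{y}-07-11", f"{y}-07-20"),
            "zhongfu": (f"{y}-07-21", f"{y}-08-09"),
            "mofu": (f"{y}-08-10", f"{y}-08-19"),
        }
        for y in years
    }
    return met_features.SanfuCalendar(periods)


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Weather plus counts in one call; seeds split deterministically."""
    rng = np.random.default_rng(config.seed)
    weather_seed, count_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    weather = generate_weather(config.with_(seed=weather_seed))
    return generate_counts(weather, config.lag_effect, config.count_baseline, count_seed)
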