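"""CSV readers/writers and pipeline configuration.

One flat date-keyed daily table is the interchange format throughout:
columns ``date`` (ISO-8601), ``tmean_c``, ``tmax_c``, ``rh_pct`` and
optionally ``count``, ``burn_in`` plus any derived feature columns. All
artifacts are plain CSV; configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .met_features import SanfuCalendar

__all__ = ["read_daily_csv", "write_daily_csv", "PipelineConfig", "load_config"]

REQUIRED_COLUMNS = ("date", "tmean_c", "tmax_c", "rh_pct")


def read_daily_csv(path, require_count: bool = False) -> pd.DataFrame:
    """Read and validate a daily series CSV.

    Checks required columns, ISO-parseable unique dates, integer
    non-negative counts (when present) and relative humidity inside
    [0, 100]; violations raise with the offending row numbers (1-based,
    excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = REQUIRED_COLUMNS + (("count",) if require_count else ())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = df.index[dates.isna()] + 1
    if len(bad):
        raise ValueError(f"{path.name}: unparseable dates at rows {list(bad[:10])}")
    dup = df.index[dates.duplicated()] + 1
    if len(dup):
        raise ValueError(f"{path.name}: duplicate dates at rows {list(dup[:10])}")
    df["date"] = dates

    rh_bad = df.index[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)] + 1
    if len(rh_bad):
        raise ValueError(f"{path.name}: relative humidity outside [0, 100] at rows {list(rh_bad[:10])}")
    if "count" in df.columns:
        cnt = pd.to_numeric(df["count"], errors="coerce")
        cnt_bad = df.index[cnt.isna() | (cnt < 0) | (cnt != cnt.round())] + 1
        if len(cnt_bad):
            raise ValueError(
                f"{path.name}: counts must be non-negative integers; bad rows {list(cnt_bad[:10])}"
            )
        df["count"] = cnt.astype(int)
    if "year" not in df.columns:
        df["year"] = df["date"].dt.year
    return df


def write_daily_csv(df: pd.DataFrame, path) -> Path:
    """Write a daily table with ISO dates; round-trips through read_daily_csv."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


_KNOWN_KEYS = {
    "seed",
    "input_csv",
    "out_dir",
    "years",
    "synthetic",
    "split",
    "exposure",
    "exposure_basis",
    "lag_basis",
    "seasonal_df",
    "boruta",
    "random_forest",
    "warning_rules",
    "sanfu_calendar",
    "holidays",
    "features",
    "arima_order",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``).

    Unknown top-level keys are rejected with a message naming them, so a
    typo never silently falls back to a default.
    """

    seed: int = 0
    input_csv: str | None = None
    out_dir: str = "results"
    synthetic: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    exposure: str = "heat_index_c"
    exposure_basis: dict = field(default_factory=dict)
    lag_basis: dict = field(default_factory=dict)
    seasonal_df: int = 10
    boruta: dict = field(default_factory=dict)
    random_forest: dict = field(default_factory=dict)
    warning_rules: dict = field(default_factory=dict)
    sanfu_calendar: dict = field(default_factory=dict)
    holidays: list = field(default_factory=list)
    features: list = field(default_factory=list)
    arima_order: tuple = (2, 0, 1)

    def calendar(self) -> SanfuCalendar | None:
        return SanfuCalendar.from_dict(self.sanfu_calendar) if self.sanfu_calendar else None

    def digest(self) -> str:
        """Stable hash of the configuration, stamped onto artifacts."""
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(source) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file path or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        raise TypeError("load_config takes a path or a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.arima_order, list):
        cfg.arima_order = tuple(cfg.arima_order)
    return cfg
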