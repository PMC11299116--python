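"""End-to-end pipeline: simulate/ingest -> features -> selection -> DLNM ->
prediction -> warnings.

Each stage is a thin orchestration over the library modules; every artifact
is a plain CSV (plus a JSON run log) stamped with the configuration hash
and seed. Any stage failure aborts with the stage name and the original
cause chained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import boruta, dlnm, io, met_features, prediction, synthetic, warning_engine

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_FEATURES"]

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = [
    "day",
    "month",
    "weekday",
    "tmean_c",
    "tmax_c",
    "rh_pct",
    "heat_index_c",
    "dew_point_c",
    "is_heatwave",
    "toufu",
    "zhongfu",
    "mofu",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(name, exc) from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("simulate")
def _simulate(cfg: io.PipelineConfig) -> pd.DataFrame:
    if cfg.input_csv:
        return io.read_daily_csv(cfg.input_csv, require_count=True)
    syn = dict(cfg.synthetic)
    if "lag_effect" in syn and isinstance(syn["lag_effect"], dict):
        syn["lag_effect"] = synthetic.TrueLagSurface(**syn["lag_effect"])
    syn.setdefault("seed", cfg.seed)
    if "years" in syn:
        syn["years"] = tuple(syn["years"])
    config = synthetic.SyntheticConfig(**syn)
    return synthetic.generate_dataset(config)


@_stage("features")
def _features(cfg: io.PipelineConfig, daily: pd.DataFrame) -> pd.DataFrame:
    calendar = cfg.calendar()
    if calendar is None:
        if cfg.input_csv:
            raise ValueError("a sanfu_calendar is required when ingesting real data")
        years = sorted(pd.to_datetime(daily["date"]).dt.year.unique())
        calendar = synthetic.synthetic_sanfu_calendar(years)
        logger.info("using the schematic synthetic sanfu calendar for years %s", years)
    return met_features.add_met_features(daily, calendar=calendar, holidays=cfg.holidays)


@_stage("select")
def _select(cfg: io.PipelineConfig, feats: pd.DataFrame) -> boruta.BorutaResult:
    usable = feats[feats.get("burn_in", 0) == 0] if "burn_in" in feats.columns else feats
    cols = [c for c in (cfg.features or DEFAULT_FEATURES) if c in usable.columns]
    bcfg = boruta.BorutaConfig(seed=cfg.seed, **cfg.boruta)
    return boruta.boruta_select(usable[cols], usable["count"], bcfg)


@_stage("dlnm")
def _dlnm(cfg: io.PipelineConfig, feats: pd.DataFrame):
    espec = dlnm.ExposureBasisSpec(**cfg.exposure_basis) if cfg.exposure_basis else dlnm.ExposureBasisSpec()
    lspec = dlnm.LagBasisSpec(**cfg.lag_basis) if cfg.lag_basis else dlnm.LagBasisSpec()
    x = feats[cfg.exposure].to_numpy(dtype=float)
    cb = dlnm.build_cross_basis(x, espec, lspec, blocks=feats["year"].to_numpy())
    fit = dlnm.fit_dlnm(
        cb,
        feats["count"].to_numpy(),
        dates=feats["date"],
        seasonal_df=cfg.seasonal_df,
        weekday=feats["weekday"].to_numpy(),
        holiday=feats["holiday"].to_numpy(),
    )
    grid = np.linspace(np.nanmin(x), np.nanmax(x), 30)
    surface = dlnm.predict_rr(fit, grid)
    return fit, surface


@_stage("predict")
def _predict(cfg: io.PipelineConfig, feats: pd.DataFrame, selected: list) -> prediction.EvalReport:
    split = prediction.SplitSpec(
        frozenset(cfg.split.get("train_years", (2014, 2015, 2016, 2017, 2018))),
        frozenset(cfg.split.get("validation_years", (2019,))),
    )
    usable = feats[feats.get("burn_in", 0) == 0] if "burn_in" in feats.columns else feats
    train, valid = split.split(usable)
    features = selected or [c for c in DEFAULT_FEATURES if c in usable.columns]
    rf_spec = prediction.RFSpec(seed=cfg.seed, **cfg.random_forest)
    return prediction.fit_predict_suite(
        train, valid, features, seed=cfg.seed, rf_spec=rf_spec, arima_order=tuple(cfg.arima_order)
    )


@_stage("warn")
def _warn(
    cfg: io.PipelineConfig, feats: pd.DataFrame, report: prediction.EvalReport
) -> tuple[warning_engine.WarningSchedule, warning_engine.WarningRules]:
    rules_kw = dict(cfg.warning_rules)
    if "count_threshold" not in rules_kw:
        # data-adaptive default: 90th percentile of training-period counts
        train_years = set(cfg.split.get("train_years", (2014, 2015, 2016, 2017, 2018)))
        train_counts = feats.loc[feats["year"].isin(train_years), "count"]
        rules_kw["count_threshold"] = float(np.percentile(train_counts, 90))
        logger.info("warning count_threshold defaulted to %.2f", rules_kw["count_threshold"])
    for key in ("rh_low_window", "rh_high_window"):
        if key in rules_kw:
            rules_kw[key] = tuple(rules_kw[key])
    rules = warning_engine.WarningRules(**rules_kw)
    pred_frame = report.predictions
    model = "random_forest" if "random_forest" in pred_frame.columns else pred_frame.columns[2]
    preds = pd.Series(pred_frame[model].to_numpy(), index=pd.DatetimeIndex(pred_frame["date"]))
    driver_cols = ["heat_index_c", "dew_point_c", "tmax_c", "rh_pct"]
    drivers = feats.set_index(pd.DatetimeIndex(feats["date"]))[driver_cols].loc[preds.index]
    return warning_engine.generate_warnings(preds, drivers, rules), rules


def run_pipeline(cfg: io.PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages in order and write the artifact set.

    Returns a dict of artifact paths plus the in-memory results. Fixed seed
    and config imply bit-identical artifacts.
    """
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.digest(), "seed": cfg.seed}

    daily = _simulate(cfg)
    io.write_daily_csv(daily, out / "daily.csv")

    feats = _features(cfg, daily)
    io.write_daily_csv(feats, out / "features.csv")

    selection = _select(cfg, feats)
    (out / "selected_features.json").write_text(
        json.dumps(
            {
                "confirmed": selection.confirmed,
                "tentative": selection.tentative,
                "rejected": selection.rejected,
                "n_iterations": selection.n_iterations_run,
                **stamp,
            },
            indent=2,
        )
    )

    fit, surface = _dlnm(cfg, feats)
    surface.to_frame().to_csv(out / "rr_surface.csv", index=False)
    surface.cumulative.to_csv(out / "rr_cumulative.csv", index=False)

    # predict with the confirmed plus still-tentative features (all-relevant
    # selection keeps undecided features); fall back to the defaults if the
    # selector rejected everything
    report = _predict(cfg, feats, (selection.confirmed + selection.tentative) or None)
    report.metrics.to_csv(out / "eval_report.csv")
    report.predictions.to_csv(out / "predictions.csv", index=False)

    schedule, rules = _warn(cfg, feats, report)
    schedule.to_frame().to_csv(out / "warnings.csv", index=False)

    log = {
        **stamp,
        "stages": ["simulate", "features", "select", "dlnm", "predict", "warn"],
        "n_days": int(len(daily)),
        "dlnm": {
            "family": fit.family,
            "dispersion": fit.dispersion,
            "centering_value": fit.centering_value,
            "deviance": fit.deviance,
            "n_obs": fit.n_obs,
        },
        "metrics": {
            m: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for m, row in report.metrics.iterrows()
        },
        "best_model": report.best_model(),
        "warning_rules": {
            "count_threshold": rules.count_threshold,
            "hi_threshold": rules.hi_threshold,
            "td_threshold": rules.td_threshold,
            "tmax_threshold": rules.tmax_threshold,
        },
        "n_warning_days": len(schedule.entries),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "out_dir": out,
        "daily": daily,
        "features": feats,
        "selection": selection,
        "fit": fit,
        "surface": surface,
        "report": report,
        "schedule": schedule,
        "log": log,
    }
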