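# heatlag

Distributed-lag non-linear modelling, count prediction and rule-based early
warning for daily heat-related illness (heatstroke) surveillance series.

Heatstroke counts respond to heat not only on the day of exposure but over
the following days and weeks, and the response is non-linear in the exposure
value. This package implements the full analysis chain used in heat-health
surveillance studies, exercised end-to-end on synthetic data with a *known*
exposure–lag–response surface so that every stage can be validated against
ground truth:

1. **Synthetic generator** — multi-year May–September daily weather
   (seasonal sinusoid + AR(1) temperature, humidity anti-correlated with
   temperature) and Poisson counts with
   `log μ_t = log(baseline) + β · Σ_l w_l · max(0, x_{t−l} − x_0)`,
   so the cumulative relative risk of exposure `x` versus the threshold
   `x_0` is exactly `exp(β · (x − x_0))`.
2. **Meteorological features** — heat index (9-coefficient Rothfusz
   regression with the NWS low-range fallback), Magnus dew point
   `T_d = b·γ/(a−γ)`, `γ = aT/(b+T) + ln(RH/100)` with `a = 17.27`,
   `b = 237.7 °C`, CMA heatwave flags (≥ 3 consecutive days with
   `T_max ≥ 35 °C`), *sanfu* calendar indicators, weekday/holiday flags.
3. **DLNM core** — cross-basis
   `cb[t,(j,k)] = Σ_{l=0}^{L} w_j(x_{t−l}) · C_k(l)` (natural-cubic-spline
   exposure basis, orthonormal polynomial lag basis, defaults df 4 / degree
   4 / L = 30), quasi-Poisson regression
   `log E[Y_t] = α + cb(x, lag) + ns(date, 10) + dow + holiday`,
   and relative-risk surfaces `RR(x, l) = exp(Δηᵀβ)` with delta-method 95 %
   CIs, per lag and cumulated over lags.
4. **Boruta feature selection** — shadow-feature all-relevant selection
   (tree depth 4, perc 100, α 0.05, two-step binomial correction, ≤ 100
   iterations), with held-out permutation importance.
5. **Prediction suite** — regression tree, the tuned 13-tree random forest
   (depth 4, leaf 1, split 4), gradient boosting, linear SVR (static
   prediction) and rolling one-step ARIMA, scored by MSE, RMSE and R²;
   grid search, feature-perturbation sensitivity analysis, and descriptive
   monthly / *sanfu*-period share statistics.
6. **Warning engine** — predicted-count trigger; 5-day reinforced warnings
   when heat index > 30 °C, dew point > 23 °C or `T_max` > 35 °C co-occur;
   delayed warnings on days d+20…d+25 after a day with RH < 65 % and
   d+22…d+28 after RH > 85 %.

## Worked example

The numbered scripts under `analysis/` run the chain on the synthetic
six-season dataset and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_features.py
python analysis/05_dlnm.py
```

prints

```
wrote results/daily.csv: 918 days over 6 seasons
mean daily count (post burn-in): 2.26
true cumulative RR at 35 degC vs threshold: 1.2840
...
fitted quasipoisson DLNM on 738 days; dispersion 1.061
cumulative RR at 35 vs 30 degC: 1.559 (95% CI 0.814-2.984); generative truth 1.284
```

i.e. the quasi-Poisson fit is essentially equidispersed (the generator is
Poisson), and the full smooth cross-basis (lags 0–30, spline exposure)
brackets the generative cumulative relative risk `exp(0.25) ≈ 1.284` within
its confidence interval on a single realisation. A correctly specified
threshold basis recovers it with ~96 % CI coverage over 100 replicates (see
the acceptance script). The remaining scripts run feature selection, the
model comparison and the warning schedule; `heatlag all --config
examples/config.yaml` chains every stage through the CLI instead.

The same library functions back the CLI subcommands
`simulate | features | select | dlnm | predict | warn | all`.

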