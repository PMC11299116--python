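# Methods

## The model

Daily heatstroke counts `Y_t` are modelled with a distributed-lag
non-linear model (DLNM):

```
log E[Y_t] = α + cb(x, lag) + ns(date, df_seas) + dow + holiday
```

`cb` is the cross-basis of the exposure series `x_t` (heat index by
default): with exposure basis functions `w_j(·)` and lag basis functions
`C_k(l)` over lags `l = 0..L`,

```
cb[t, (j,k)] = Σ_{l=0}^{L} w_j(x_{t−l}) · C_k(l).
```

The coefficients on these columns encode a full exposure–lag–response
surface. Relative risks are linear-predictor contrasts against a centering
exposure `x_ref`: `RR(x, l) = exp(d′β)` with
`d = [w(x) − w(x_ref)] ⊗ C(l)`, variance `d′Σd` by the delta method, and
the cumulative RR sums the log-RR over the lag grid before exponentiating.
At `x = x_ref` the contrast is identically zero, so `RR ≡ 1` — this holds
by construction for every fit and is asserted in the tests.

Counts are overdispersed in most surveillance data, so the default family
is quasi-Poisson: Poisson point estimates with the covariance scaled by the
Pearson dispersion `φ̂` (statsmodels GLM, `scale="X2"`). On the package's
equidispersed synthetic data `φ̂ ≈ 1`, which the tests check.

### Basis choices

- **Lag basis**: polynomial in the lag index, degree 4, maximum lag 30 by
  default. The raw polynomial columns are numerically hostile at L = 30, so
  they are orthonormalised by QR over the lag grid; predictions are
  invariant to this reparameterisation. The degree must not exceed the
  number of lag points minus one (validated).
- **Exposure basis**: configurable — natural cubic spline (default, df 4,
  quantile knots), simple polynomial, identity, or a linear-threshold
  (hinge) term. The spline default matches common DLNM practice and
  reproduces smooth J-shaped risk curves; the hinge basis is the correctly
  specified choice when the generative surface itself is threshold-linear.
- **Seasonality**: a natural cubic spline on the within-study day index,
  df 10 by default, plus weekday indicator contrasts (reference Monday) and
  a holiday indicator (dropped automatically when no holidays are
  configured, since an all-zero column is vacuous and singular).
- **Centering**: defaults to the median observed exposure so the reference
  is interior; configurable. CIs are fixed at 95 % (z = 1.96).

### Natural spline implementation

The basis is built from cubic B-splines (scipy) with the two boundary
second-derivative constraints projected out via the orthonormal null space
of the constraint matrix, and linear first-order continuation beyond the
boundary knots. Because any such construction spans the same function
space, the cross-library check against R's `splines::ns` compares
least-squares *fitted values* (basis-invariant), frozen once into the test
suite; agreement is at 1e-8.

## Synthetic data: what it emulates and what it does not

`heatlag.synthetic` generates May–September series for a configurable set
of years. Daily mean temperature is an annual sinusoid (base 24 °C,
half-swing 5 °C, peak around day 205) plus AR(1) noise (innovation sd
1.5 °C, coefficient 0.6, restarted at stationarity each season); the daily
maximum adds a mean 5.5 °C half-normal offset and never drops below the
mean; relative humidity couples linearly to the temperature anomaly
(−1.5 %/°C) with sd 8 %, clipped to [5, 100]. These values were calibrated
once against south-China warm-season climatology (in-season means ~20–31 °C,
median Tmax ≈ 33 °C, ~12 % of days in CMA heatwave, about half of days
above the 30 °C heat-index threshold) and are not tuned thereafter.

Counts are Poisson with the threshold-linear log-rate

```
log μ_t = log(baseline) + slope · Σ_l w_l · max(0, x_{t−l} − threshold)
```

(default: heat-index exposure, threshold 30 °C, slope 0.05, weights
decaying geometrically over lags 0–5 and summing to one). The closed form
`cumRR(x) = exp(slope · (x − threshold)⁺)` is the ground truth every
recovery experiment targets. A hook accepts arbitrary user rate functions,
and a negative-binomial switch produces overdispersed counts. The first
`L` days of each season are flagged `burn_in` and excluded from fitting.

The generator does **not** emulate: spatial structure, humidity
microphysics, reporting artefacts (weekday/holiday under-reporting — those
covariates carry no true effect here), population change, or a genuine
humidity→risk lag at 20–28 days. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
epidemiological validity on any real city's data.

## Recovery experiments and their design

The headline check fits the DLNM to five-season replicates and asks
whether the 95 % CI of the cumulative RR at 35 °C (reference 30 °C) covers
the generative truth `exp(0.25)` in ≥ 90 % of 100 replicates. The fit uses
the linear-threshold exposure basis at the known 30 °C threshold with the
polynomial lag basis over L = 10 (> the true maximum lag 5): a correctly
specified mean structure, so the CI calibration of the
quasi-Poisson/delta-method machinery is what is actually under test.
Measured coverage is ~96 %. The smooth ns-basis fit is checked separately
as a bias test: its cumulative log-RR estimate approaches the truth as the
series grows (spline approximation of a hinge incurs finite-sample bias
that shrinks with data).

## Boruta

Implemented from scratch: each iteration permutes every feature into a
shadow copy (padded to at least five shadows), fits a depth-4 random
forest (auto size `100·√(2p)/depth`, mtry = p/3) on the augmented matrix,
and scores a hit when a real feature's importance exceeds the `perc`-th
percentile (default: maximum) of the shadow importances. Accumulated hits
are tested against Binomial(n, ½); with `two_step` a Benjamini–Hochberg
gate across features is combined with a Bonferroni gate across iterations
for both confirmation and rejection, the reference two-step scheme.

The importance measure is **permutation importance on a per-iteration
held-out split** (default 30 %). In-sample impurity importance is offered
as an option but is not the default: at n = 500 a pure-noise feature with
chance correlation ≈ 0.1 is genuinely *in-sample* relevant, beats its
freshly permuted shadows persistently, and gets falsely confirmed in
roughly a third of runs. Held-out scoring restores the exchangeability the
binomial null assumes — the same rationale as out-of-bag
mean-decrease-accuracy in the classic algorithm — and the null simulation
(5 noise features) then confirms nothing in 20/20 seeded runs while an
informative feature is confirmed in 20/20.

On the default synthetic data the weather drivers are strongly collinear
(heat index is a function of temperature and humidity), so Boruta may
leave them *tentative* rather than confirmed — the correct all-relevant
behaviour under shared importance. Downstream prediction therefore uses
confirmed ∪ tentative features.

## Prediction suite

Tabular models are trained once on the training years (2014–2018 by
default) and predict the validation season (2019) statically; the tuned
random forest is 13 trees of depth 4 (leaf 1, split 4), whose prediction
is the plain average over trees. ARIMA ignores the covariates and rolls
one-step-ahead: fitted once on the training series, then extended through
the validation season by filtering (no daily refit), each forecast using
history up to the previous day. The default order (2,0,1) with constant
was chosen by a small grid on synthetic pilots; the order is exposed in
configuration. LSTM is a plugin slot only — any fitted-predictor object
can be passed into the suite — since no neural-network stack is a
dependency. Metrics are MSE, RMSE = √MSE and R² = 1 − SSres/SStot; a
constant observation series leaves R² undefined and is reported as such.

Descriptive shares are `100·group/overall`, rounded half-up to two
decimals (this convention reproduces published monthly percentages
exactly, e.g. 1753/2964 → 59.14 %).

## Warning engine

Deterministic rules over aligned daily predictions and drivers; levels
`none < warning < reinforced`, overlaps merge to the maximum, every entry
carries (rule, origin-date) provenance, and delayed windows are inclusive
on both ends and may extend past the data horizon as future-dated entries.
The count threshold is data-adaptive by default (90th percentile of
training counts) and recorded in the run log. The delayed humidity rules
fire independently of the count trigger: the mechanism's medium-humidity
band (65–78 %) acts through same-day reinforcement only. Raising any
threshold can only remove warnings (tested as a monotonicity property).

## Numerical and engineering notes

- All randomness flows from explicit `numpy.random.Generator` seeds; no
  global RNG state anywhere. Identical config + seed ⇒ bit-identical
  artifacts (tested).
- GLM convergence tolerance is tightened to 1e-12 so Poisson and
  quasi-Poisson runs agree to numerical precision.
- The cross-basis masks rows with incomplete lag history (season starts,
  missing exposure) instead of imputing; blocks (years) never share lag
  windows.
- CSV is the only artifact format; the reader validates dates, humidity
  range and count integrality with row-numbered errors and uses
  round-trip float parsing.
- Test problem sizes (five-season replicates, 100 coverage replicates, 20
  Boruta runs, n = 500) mirror the scale of the motivating six-season
  surveillance dataset while keeping the default suite a desk-scale run.

## Known limitations

- The heat-index polynomial ships with the Rothfusz coefficient set
  (Fahrenheit-native, converted at the interface); alternate coefficient
  sets can be injected but no other published set is bundled.
- The *sanfu* calendar must be supplied for real analyses; the packaged
  calendar is an explicitly schematic synthetic stand-in with fixed dates
  each year, not the lunar-calendar truth.
- ARIMA refitting is filter-based between days; a full daily re-estimation
  would be slower and was not needed for the one-step contract.
- The DLNM assumes a single exposure per fit; multi-exposure models are
  run one exposure at a time, as in the motivating analysis.
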