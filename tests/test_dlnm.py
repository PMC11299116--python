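"""Cross-basis construction, (quasi-)Poisson fitting and RR surfaces."""

import numpy as np
import pandas as pd
import pytest

from heatlag import met_features
from heatlag.dlnm import (
    CrossBasis,
    ExposureBasisSpec,
    LagBasisSpec,
    build_cross_basis,
    cross_basis_bruteforce,
    fit_dlnm,
    predict_rr,
)
from heatlag.synthetic import SyntheticConfig, TrueLagSurface, generate_dataset


def _random_specs(rng):
    espec = ExposureBasisSpec(
        kind=rng.choice(["ns", "poly", "linear", "threshold"]),
        df=int(rng.integers(1, 4)),
        threshold=float(rng.normal(30, 2)),
    )
    max_lag = int(rng.integers(2, 8))
    lspec = LagBasisSpec(max_lag=max_lag, degree=int(rng.integers(1, min(4, max_lag + 1))))
    return espec, lspec


class TestCrossBasis:
    def test_constant_exposure_gives_identical_rows(self):
        cb = build_cross_basis(
            np.full(40, 31.0), ExposureBasisSpec("poly", df=2), LagBasisSpec(5, 2)
        )
        rows = cb.matrix[cb.valid_mask]
        np.testing.assert_allclose(rows - rows[0], 0.0, atol=1e-10)

    def test_identity_basis_lag0_indicator_recovers_series(self, rng):
        # identity exposure basis and a lag basis collapsed to the lag-0
        # indicator reproduce x_t itself
        x = rng.normal(30, 3, 30)
        espec = ExposureBasisSpec("linear")
        lspec = LagBasisSpec(max_lag=4, degree=4)
        cb = build_cross_basis(x, espec, lspec)
        # form the lag-0 indicator in the orthonormal lag basis: C C^T e_0
        e0 = np.zeros(5)
        e0[0] = 1.0
        coef = cb.lag_matrix.T @ e0  # lag basis is square and orthonormal here
        combo = cb.matrix[cb.valid_mask] @ coef
        np.testing.assert_allclose(combo, x[cb.valid_mask], atol=1e-10)

    def test_first_max_lag_rows_masked_per_block(self, rng):
        x = rng.normal(size=30)
        blocks = [0] * 15 + [1] * 15
        cb = build_cross_basis(x, ExposureBasisSpec("linear"), LagBasisSpec(5, 2), blocks=blocks)
        expected = np.array(([False] * 5 + [True] * 10) * 2)
        np.testing.assert_array_equal(cb.valid_mask, expected)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            build_cross_basis(np.arange(10.0), lag_spec=LagBasisSpec(30, 4))

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(30, 4, 60)
        espec, lspec = _random_specs(rng)
        cb = build_cross_basis(x, espec, lspec)
        np.testing.assert_allclose(cb.matrix, cross_basis_bruteforce(x, cb), atol=1e-10)


def _fit_on(df, espec=None, lspec=None, centering=None):
    x = met_features.heat_index(df["tmean_c"].to_numpy(), df["rh_pct"].to_numpy())
    cb = build_cross_basis(
        x,
        espec or ExposureBasisSpec("threshold", threshold=30.0),
        lspec or LagBasisSpec(10, 4),
        blocks=df["year"].to_numpy(),
    )
    return cb, fit_dlnm(
        cb,
        df["count"].to_numpy(),
        dates=df["date"],
        seasonal_df=10,
        weekday=df["date"].dt.weekday.to_numpy(),
        centering_value=centering,
    )


class TestFit:
    def test_constant_counts_closed_form(self):
        # when every count equals k the Poisson score equations are solved
        # exactly by mu = k: intercept log k, all other coefficients zero
        n = 80
        rng = np.random.default_rng(3)
        cb = build_cross_basis(rng.normal(32, 2, n),
                               ExposureBasisSpec("threshold", threshold=30.0),
                               LagBasisSpec(3, 1))
        fit = fit_dlnm(cb, np.full(n, 7), seasonal_df=0, family="poisson")
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(7), abs=1e-6)
        np.testing.assert_allclose(fit.cb_coefficients, 0.0, atol=1e-5)

    def test_quasipoisson_scales_covariance_only(self, five_season_dataset):
        df = five_season_dataset
        _, fit_q = _fit_on(df)
        x = met_features.heat_index(df["tmean_c"].to_numpy(), df["rh_pct"].to_numpy())
        cb = build_cross_basis(x, ExposureBasisSpec("threshold", threshold=30.0),
                               LagBasisSpec(10, 4), blocks=df["year"].to_numpy())
        fit_p = fit_dlnm(cb, df["count"].to_numpy(), dates=df["date"], seasonal_df=10,
                         weekday=df["date"].dt.weekday.to_numpy(), family="poisson")
        np.testing.assert_allclose(fit_q.coefficients, fit_p.coefficients, atol=1e-6)
        # IRLS stopping points may differ in the last iterate, so compare the
        # scaling identity cov_q = phi * cov_p only up to that numerical slack
        np.testing.assert_allclose(
            fit_q.covariance, fit_p.covariance * fit_q.dispersion, rtol=1e-3
        )

    def test_dispersion_near_one_on_equidispersed_data(self, five_season_dataset):
        _, fit = _fit_on(five_season_dataset)
        assert fit.dispersion == pytest.approx(1.0, abs=0.15)

    def test_counts_must_align(self, five_season_dataset):
        df = five_season_dataset
        x = df["tmean_c"].to_numpy()
        cb = build_cross_basis(x, ExposureBasisSpec("linear"), LagBasisSpec(5, 2))
        with pytest.raises(ValueError, match="align"):
            fit_dlnm(cb, df["count"].to_numpy()[:-5])

    def test_collinear_design_named(self):
        # a constant exposure makes every cross-basis column constant, hence
        # collinear with the intercept: the fit must refuse, naming columns
        n = 120
        rng = np.random.default_rng(0)
        cb = build_cross_basis(np.full(n, 33.0), ExposureBasisSpec("linear"), LagBasisSpec(3, 1))
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_dlnm(cb, rng.poisson(2, n), seasonal_df=0)


class TestRRSurface:
    def test_centering_identity(self, five_season_dataset):
        _, fit = _fit_on(five_season_dataset, espec=ExposureBasisSpec("ns", df=4))
        rr = predict_rr(fit, [fit.centering_value], lag_grid=list(range(11)))
        np.testing.assert_allclose(rr.rr, 1.0, atol=1e-12)
        assert np.all(rr.rr_low <= 1.0 + 1e-12) and np.all(rr.rr_high >= 1.0 - 1e-12)
        row = rr.cumulative.iloc[0]
        assert row["rr"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_coefficients_give_flat_surface(self, five_season_dataset):
        _, fit = _fit_on(five_season_dataset)
        fit.coefficients[fit.cb_slice] = 0.0
        rr = predict_rr(fit, [25.0, 32.0, 38.0])
        np.testing.assert_allclose(rr.rr, 1.0, atol=1e-12)

    def test_ci_brackets_point_estimate(self, five_season_dataset):
        _, fit = _fit_on(five_season_dataset)
        rr = predict_rr(fit, np.linspace(22, 40, 7))
        assert np.all(rr.rr_low <= rr.rr) and np.all(rr.rr <= rr.rr_high)
        assert np.all(rr.rr > 0)

    def test_reference_outside_range_warns(self, five_season_dataset):
        _, fit = _fit_on(five_season_dataset)
        with pytest.warns(UserWarning, match="outside"):
            predict_rr(fit, [30.0], reference=-50.0)


class TestRecovery:
    def test_cumulative_rr_coverage(self, default_surface):
        """The fitted cumulative RR at exposure 35 covers exp(0.25) in >=90%
        of seeded replicates (threshold-linear truth, geometric lags 0-5)."""
        truth = default_surface.cumulative_rr(35.0)
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            cfg = SyntheticConfig(seed=5000 + rep, years=tuple(range(2014, 2019)),
                                  lag_effect=default_surface)
            df = generate_dataset(cfg)
            _, fit = _fit_on(df, centering=30.0)
            row = predict_rr(fit, [35.0], reference=30.0).cumulative.iloc[0]
            hits += row["rr_low"] <= truth <= row["rr_high"]
        assert hits >= 90

    def test_bias_shrinks_with_sample_size(self, default_surface):
        """Smooth-basis fit: the cumulative log-RR estimate approaches the
        generative truth as the series grows."""
        truth = np.log(default_surface.cumulative_rr(35.0))
        errors = []
        for years in (tuple(range(2014, 2016)), tuple(range(2004, 2019))):
            ests = []
            for rep in range(5):
                cfg = SyntheticConfig(seed=900 + rep, years=years, lag_effect=default_surface)
                df = generate_dataset(cfg)
                _, fit = _fit_on(df, espec=ExposureBasisSpec("ns", df=4), centering=30.0)
                ests.append(np.log(predict_rr(fit, [35.0], reference=30.0)
                                   .cumulative["rr"].iloc[0]))
            errors.append(abs(np.mean(ests) - truth))
        assert errors[1] < max(errors[0], 0.05)
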