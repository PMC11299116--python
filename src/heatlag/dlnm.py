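"""Distributed-lag non-linear model (DLNM) core.

A DLNM represents the effect of an exposure series x_t on a count outcome
jointly over the exposure value and over lag time. The design columns are a
*cross-basis*: with exposure basis functions w_j(.) and lag basis functions
C_k(l) over lags l = 0..L, day t contributes

    cb[t, (j,k)] = sum_{l=0}^{L} w_j(x_{t-l}) * C_k(l).

The fitted model is a (quasi-)Poisson regression

    log E[Y_t] = alpha + cb(x, lag) + ns(date, df) + weekday + holiday,

and relative risks are differences of the fitted linear predictor between an
exposure value and a centering reference, per lag and cumulated over lags,
with delta-method confidence intervals.

The lag basis is a polynomial in the lag index (degree configurable, default
4, maximum lag default 30), orthonormalised over the lag grid for
conditioning; predictions are invariant to that reparameterisation. The
exposure basis is configurable: natural cubic spline (default), simple
polynomial, identity, or a linear-threshold (hinge) term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import NaturalSpline, natural_spline_basis

__all__ = [
    "LagBasisSpec",
    "ExposureBasisSpec",
    "CrossBasis",
    "DLNMFit",
    "RRSurface",
    "build_cross_basis",
    "fit_dlnm",
    "predict_rr",
    "cross_basis_bruteforce",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class LagBasisSpec:
    """Polynomial basis over the lag dimension 0..max_lag."""

    max_lag: int = 30
    degree: int = 4
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.degree < 1:
            raise ValueError("lag polynomial degree must be >= 1")
        if self.degree > self.max_lag:
            raise ValueError(
                f"lag polynomial degree {self.degree} exceeds max_lag {self.max_lag}: "
                "the basis would be rank-deficient on the lag grid"
            )

    @property
    def df(self) -> int:
        return self.degree + (1 if self.intercept else 0)

    def basis_matrix(self) -> np.ndarray:
        """(max_lag+1, df) orthonormal polynomial basis over the lag grid."""
        lags = np.arange(self.max_lag + 1, dtype=float) / self.max_lag
        raw = np.vander(lags, self.degree + 1, increasing=True)
        q, r = np.linalg.qr(raw)
        q = q * np.sign(np.diag(r))  # fix QR sign convention
        return q if self.intercept else q[:, 1:]


@dataclass(frozen=True)
class ExposureBasisSpec:
    """Basis over the exposure dimension.

    kind: 'ns' (natural cubic spline, default), 'poly', 'linear' (identity),
    or 'threshold' (hinge max(0, x - threshold), df 1). Knots for 'ns' are
    placed at quantiles of the observed exposure unless given explicitly.
    """

    kind: str = "ns"
    df: int = 4
    knots: tuple | None = None
    boundary_knots: tuple | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ns", "poly", "linear", "threshold"):
            raise ValueError(f"unknown exposure basis kind {self.kind!r}")
        if self.df < 1:
            raise ValueError("exposure basis df must be >= 1")
        if self.knots is not None and np.any(np.diff(self.knots) <= 0):
            raise ValueError("exposure knots must be strictly increasing")
        if self.kind == "threshold" and self.threshold is None:
            raise ValueError("threshold basis requires a threshold value")


class _ExposureBasis:
    """Realised exposure basis: transforms exposure values to w_j columns."""

    def __init__(self, spec: ExposureBasisSpec, x: np.ndarray):
        self.spec = spec
        x = np.asarray(x, dtype=float)
        if spec.kind == "ns":
            self._ns = NaturalSpline.fit(
                x[np.isfinite(x)], spec.df, knots=spec.knots, boundary_knots=spec.boundary_knots
            )
            self.df = spec.df
        elif spec.kind == "poly":
            self._scale = (float(np.nanmin(x)), float(np.nanmax(x)))
            self.df = spec.df
        elif spec.kind == "linear":
            self.df = 1
        elif spec.kind == "threshold":
            self.df = 1

    def transform(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.spec.kind == "ns":
            return self._ns.design_matrix(v)
        if self.spec.kind == "poly":
            lo, hi = self._scale
            u = (v - lo) / (hi - lo) if hi > lo else v
            return np.column_stack([u ** (p + 1) for p in range(self.spec.df)])
        if self.spec.kind == "linear":
            return v[:, None].copy()
        return np.maximum(0.0, v - self.spec.threshold)[:, None]


@dataclass
class CrossBasis:
    """Per-day cross-basis design for a single exposure series.

    ``matrix`` has one row per day and df_exposure*df_lag columns; rows whose
    lag window is incomplete (start of the series / of a contiguous block, or
    containing missing exposure) are flagged False in ``valid_mask`` and
    zero-filled, never imputed.
    """

    matrix: np.ndarray
    exposure_spec: ExposureBasisSpec
    lag_spec: LagBasisSpec
    exposure_series: np.ndarray
    valid_mask: np.ndarray
    exposure_basis: _ExposureBasis = field(repr=False)
    lag_matrix: np.ndarray = field(repr=False)
    column_labels: list = field(default_factory=list)

    @property
    def df_exposure(self) -> int:
        return self.exposure_basis.df

    @property
    def df_lag(self) -> int:
        return self.lag_spec.df


def build_cross_basis(
    x: Sequence[float],
    exposure_spec: ExposureBasisSpec = ExposureBasisSpec(),
    lag_spec: LagBasisSpec = LagBasisSpec(),
    blocks: Sequence | None = None,
) -> CrossBasis:
    """Build the cross-basis matrix for exposure series x.

    ``blocks`` optionally labels contiguous stretches (e.g. the year of each
    May-September season); the lag window never crosses a block boundary, so
    the first max_lag days of every block are masked.
    """
    x = np.asarray(x, dtype=float)
    L = lag_spec.max_lag
    if len(x) <= L:
        raise ValueError(f"series length {len(x)} must exceed max_lag {L}")
    eb = _ExposureBasis(exposure_spec, x)
    C = lag_spec.basis_matrix()  # (L+1, df_lag)
    W = eb.transform(x)  # (n, df_exposure)
    W = np.where(np.isfinite(W), W, np.nan)

    n, J, K = len(x), eb.df, lag_spec.df
    if blocks is None:
        block_arr = np.zeros(n, dtype=int)
    else:
        block_arr = np.asarray(pd.factorize(np.asarray(blocks))[0])
        if len(block_arr) != n:
            raise ValueError("blocks must align with the exposure series")

    pos_in_block = np.empty(n, dtype=int)
    pos = 0
    for i in range(n):
        pos = 0 if i == 0 or block_arr[i] != block_arr[i - 1] else pos + 1
        pos_in_block[i] = pos

    mat = np.zeros((n, J * K))
    valid = pos_in_block >= L
    for t in np.where(valid)[0]:
        win = W[t - L : t + 1][::-1]  # row l = w(x_{t-l})
        if not np.all(np.isfinite(win)):
            valid[t] = False
            continue
        mat[t] = (win.T @ C).ravel()  # (J, K) -> row-major j*K+k
    mat[~valid] = 0.0
    labels = [f"cb_e{j}_l{k}" for j in range(J) for k in range(K)]
    return CrossBasis(mat, exposure_spec, lag_spec, x, valid, eb, C, labels)


def cross_basis_bruteforce(
    x: Sequence[float], cb: CrossBasis
) -> np.ndarray:
    """Reference triple-loop evaluation of the cross-basis (testing oracle).

    Recomputes every valid entry as the literal sum over lags of
    w_j(x_{t-l}) * C_k(l) using the same realised basis functions.
    """
    x = np.asarray(x, dtype=float)
    L = cb.lag_spec.max_lag
    J, K = cb.df_exposure, cb.df_lag
    out = np.zeros((len(x), J * K))
    for t in range(len(x)):
        if not cb.valid_mask[t]:
            continue
        for j in range(J):
            for k in range(K):
                s = 0.0
                for l in range(L + 1):
                    s += cb.exposure_basis.transform(np.array([x[t - l]]))[0, j] * cb.lag_matrix[l, k]
                out[t, j * K + k] = s
    return out


@dataclass
class DLNMFit:
    """Fitted DLNM: coefficients, covariance, dispersion and bookkeeping."""

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    centering_value: float
    family: str
    design_labels: list
    converged: bool
    deviance: float
    cross_basis: CrossBasis
    cb_slice: slice
    n_obs: int

    @property
    def cb_coefficients(self) -> np.ndarray:
        return self.coefficients[self.cb_slice]

    @property
    def cb_covariance(self) -> np.ndarray:
        return self.covariance[self.cb_slice, self.cb_slice]


def _design_matrix(
    cb: CrossBasis,
    dates: pd.DatetimeIndex | None,
    seasonal_df: int,
    weekday: np.ndarray | None,
    holiday: np.ndarray | None,
):
    n = cb.matrix.shape[0]
    cols = [np.ones((n, 1))]
    labels = ["intercept"]
    cb_start = 1
    cols.append(cb.matrix)
    labels += cb.column_labels
    if seasonal_df and dates is not None:
        t_idx = np.arange(n, dtype=float)
        cols.append(natural_spline_basis(t_idx, seasonal_df))
        labels += [f"ns_date_{i}" for i in range(seasonal_df)]
    if weekday is not None:
        wd = np.asarray(weekday, dtype=int)
        dummies = np.column_stack([(wd == d).astype(float) for d in range(1, 7)])
        cols.append(dummies)
        labels += [f"dow_{d}" for d in range(1, 7)]
    if holiday is not None:
        h = np.asarray(holiday, dtype=float)
        if np.ptp(h) > 0:  # an all-zero indicator would be vacuous and singular
            cols.append(h[:, None])
            labels.append("holiday")
    X = np.hstack(cols)
    return X, labels, slice(cb_start, cb_start + cb.matrix.shape[1])


def fit_dlnm(
    cb: CrossBasis,
    counts: Sequence[int],
    dates: Sequence | None = None,
    seasonal_df: int = 10,
    weekday: Sequence[int] | None = None,
    holiday: Sequence[int] | None = None,
    family: str = "quasipoisson",
    centering_value: float | None = None,
) -> DLNMFit:
    """Fit log E[Y_t] = a + cb(x,lag) + ns(date,df) + dow + holiday by IRLS.

    ``family`` 'poisson' or 'quasipoisson'; the latter keeps the Poisson
    point estimates and scales the covariance by the Pearson dispersion.
    Rows masked in the cross-basis are dropped. The centering value defaults
    to the median observed exposure over the fitted rows.
    """
    y = np.asarray(counts)
    if len(y) != cb.matrix.shape[0]:
        raise ValueError("counts must align with the cross-basis rows")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if family not in ("poisson", "quasipoisson"):
        raise ValueError(f"unknown family {family!r}")

    didx = pd.DatetimeIndex(pd.to_datetime(list(dates))) if dates is not None else None
    X, labels, cb_slice = _design_matrix(cb, didx, seasonal_df, weekday, holiday)
    m = cb.valid_mask
    Xv, yv = X[m], np.asarray(y, dtype=float)[m]
    if Xv.shape[0] < Xv.shape[1] + 10:
        raise ValueError(
            f"only {Xv.shape[0]} complete rows for {Xv.shape[1]} parameters; need at least 10 more"
        )
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the columns involved in the rank deficiency
        _, r = np.linalg.qr(Xv)
        bad = [labels[i] for i in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise ValueError(f"design matrix is singular; collinear columns near {bad}")

    model = sm.GLM(yv, Xv, family=sm.families.Poisson())
    scale = "X2" if family == "quasipoisson" else 1.0
    res = model.fit(scale=scale, maxiter=200, tol=1e-12)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError("DLNM fit did not converge")

    if centering_value is None:
        centering_value = float(np.median(cb.exposure_series[m]))
    return DLNMFit(
        coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        centering_value=centering_value,
        family=family,
        design_labels=labels,
        converged=converged,
        deviance=float(res.deviance),
        cross_basis=cb,
        cb_slice=cb_slice,
        n_obs=int(m.sum()),
    )


@dataclass
class RRSurface:
    """Relative-risk surface over (exposure, lag) with 95% CIs.

    ``rr[i, k]`` is the relative risk at exposure_grid[i] and lag_grid[k]
    versus the centering reference; ``cumulative`` frames the lag-summed
    (on the log scale) risk per exposure value.
    """

    exposure_grid: np.ndarray
    lag_grid: np.ndarray
    rr: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    cumulative: pd.DataFrame
    reference: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format (exposure, lag, rr, rr_low, rr_high) table."""
        e, l = np.meshgrid(self.exposure_grid, self.lag_grid, indexing="ij")
        return pd.DataFrame(
            {
                "exposure": e.ravel(),
                "lag": l.ravel(),
                "rr": self.rr.ravel(),
                "rr_low": self.rr_low.ravel(),
                "rr_high": self.rr_high.ravel(),
            }
        )


def predict_rr(
    fit: DLNMFit,
    exposure_grid: Sequence[float],
    lag_grid: Sequence[int] | None = None,
    reference: float | None = None,
) -> RRSurface:
    """Lag-specific and cumulative relative risks with delta-method CIs.

    RR(x, l) = exp(d'b) with d = [w(x) - w(ref)] (x) C(l) restricted to the
    cross-basis columns; the cumulative RR sums the log-RR over the lag grid
    before exponentiating. CI level is fixed at 95%.
    """
    cb = fit.cross_basis
    ref = fit.centering_value if reference is None else float(reference)
    xs = np.asarray(exposure_grid, dtype=float)
    obs = cb.exposure_series[np.isfinite(cb.exposure_series)]
    if not (obs.min() <= ref <= obs.max()):
        import warnings

        warnings.warn(
            f"reference {ref} lies outside the observed exposure range "
            f"[{obs.min():.3g}, {obs.max():.3g}]",
            stacklevel=2,
        )
    lags = (
        np.arange(cb.lag_spec.max_lag + 1)
        if lag_grid is None
        else np.asarray(lag_grid, dtype=int)
    )
    if np.any(lags < 0) or np.any(lags > cb.lag_spec.max_lag):
        raise ValueError("lag grid must lie within 0..max_lag")

    W = cb.exposure_basis.transform(xs) - cb.exposure_basis.transform(np.full(len(xs), ref))
    C = cb.lag_matrix[lags]  # (n_lag, df_lag)
    beta = fit.cb_coefficients
    sigma = fit.cb_covariance

    J, K = cb.df_exposure, cb.df_lag
    # contrast vector per (x, lag): d[(j,k)] = W[x, j] * C[lag, k]
    D = np.einsum("ij,lk->iljk", W, C).reshape(len(xs), len(lags), J * K)
    eta = D @ beta
    var = np.einsum("ilp,pq,ilq->il", D, sigma, D)
    se = np.sqrt(np.maximum(var, 0.0))
    rr = np.exp(eta)
    rr_low = np.exp(eta - _Z95 * se)
    rr_high = np.exp(eta + _Z95 * se)

    Dc = D.sum(axis=1)  # cumulative contrast over the lag grid
    eta_c = Dc @ beta
    se_c = np.sqrt(np.maximum(np.einsum("ip,pq,iq->i", Dc, sigma, Dc), 0.0))
    cumulative = pd.DataFrame(
        {
            "exposure": xs,
            "rr": np.exp(eta_c),
            "rr_low": np.exp(eta_c - _Z95 * se_c),
            "rr_high": np.exp(eta_c + _Z95 * se_c),
        }
    )
    return RRSurface(xs, lags, rr, rr_low, rr_high, cumulative, ref)
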