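"""Natural cubic spline basis.

Builds the regression basis used to control seasonal/long-term trends and to
model the exposure dimension of the cross-basis: a cubic B-spline basis
constrained to be linear beyond the boundary knots (zero second derivative),
the classical "natural" spline. Outside the boundary knots the basis is
continued linearly by first-order Taylor expansion at the boundary, so
predictions extrapolate linearly, never cubically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["NaturalSpline", "natural_spline_basis"]


def _bspline_design(knot_vector: np.ndarray, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Cubic B-spline design matrix (rows: x, cols: basis functions)."""
    n_basis = len(knot_vector) - 4
    out = np.empty((len(x), n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        spl = BSpline(knot_vector, c, 3, extrapolate=False)
        if deriv:
            spl = spl.derivative(deriv)
        out[:, j] = spl(x)
    return np.nan_to_num(out)


@dataclass(frozen=True)
class NaturalSpline:
    """A fitted natural-spline basis, reusable for prediction on new x.

    ``df`` columns; interior knots at quantiles unless given. With
    ``intercept=False`` (default) the basis spans the spline space modulo the
    constant, as appropriate alongside a regression intercept.
    """

    knots: tuple
    boundary_knots: tuple
    intercept: bool = False

    @classmethod
    def fit(
        cls,
        x,
        df: int,
        knots=None,
        boundary_knots=None,
        intercept: bool = False,
    ) -> "NaturalSpline":
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("natural spline: x must be finite")
        if df < 1:
            raise ValueError("natural spline: df must be >= 1")
        if boundary_knots is None:
            boundary_knots = (float(np.min(x)), float(np.max(x)))
        if knots is None:
            n_interior = df - 1 + (0 if not intercept else -1)
            n_interior = max(n_interior, 0)
            if n_interior:
                probs = np.linspace(0, 1, n_interior + 2)[1:-1]
                interior = np.quantile(x[(x >= boundary_knots[0]) & (x <= boundary_knots[1])], probs)
            else:
                interior = np.array([])
        else:
            interior = np.asarray(knots, dtype=float)
        if len(np.unique(np.concatenate([interior, boundary_knots]))) != len(interior) + 2:
            raise ValueError(
                "natural spline: knots must be distinct and inside the boundary; "
                "is x degenerate (too few distinct values for the requested df)?"
            )
        if np.any(np.diff(interior) <= 0):
            raise ValueError("natural spline: interior knots must be strictly increasing")
        ns = cls(tuple(interior), (float(boundary_knots[0]), float(boundary_knots[1])), intercept)
        if ns.df != (df if knots is None else ns.df):
            raise ValueError("natural spline: knot placement inconsistent with df")
        return ns

    @property
    def _knot_vector(self) -> np.ndarray:
        b0, b1 = self.boundary_knots
        return np.concatenate([[b0] * 4, self.knots, [b1] * 4])

    @property
    def df(self) -> int:
        # interior knots + 2 boundary constraints absorbed: K+4 B-splines
        # minus 2 natural constraints, minus 1 if no intercept
        return len(self.knots) + 2 - (0 if self.intercept else 1)

    def _null_projector(self) -> np.ndarray:
        kv = self._knot_vector
        const = _bspline_design(kv, np.asarray(self.boundary_knots, dtype=float), deriv=2)
        if not self.intercept:
            const = const[:, 1:]
        # orthonormal basis of the null space of the boundary-curvature constraints
        q, _ = np.linalg.qr(const.T, mode="complete")
        return q[:, 2:]

    def design_matrix(self, x) -> np.ndarray:
        """Evaluate the basis at x (linear continuation beyond the boundary)."""
        x = np.asarray(x, dtype=float)
        b0, b1 = self.boundary_knots
        kv = self._knot_vector
        inside = np.clip(x, b0, b1)
        basis = _bspline_design(kv, inside)
        deriv = _bspline_design(kv, inside, deriv=1)
        below, above = x < b0, x > b1
        if np.any(below):
            basis[below] += (x[below] - b0)[:, None] * deriv[below]
        if np.any(above):
            basis[above] += (x[above] - b1)[:, None] * deriv[above]
        if not self.intercept:
            basis = basis[:, 1:]
        return basis @ self._null_projector()


def natural_spline_basis(
    x, df: int, knots=None, boundary_knots=None, intercept: bool = False
) -> np.ndarray:
    """Natural cubic spline design matrix with ``df`` columns.

    Interior knots default to quantiles of x; the basis is linear beyond the
    boundary knots. Raises on degenerate x (fewer distinct values than the
    requested df needs).
    """
    ns = NaturalSpline.fit(x, df, knots=knots, boundary_knots=boundary_knots, intercept=intercept)
    mat = ns.design_matrix(np.asarray(x, dtype=float))
    if mat.shape[1] != df:
        raise ValueError(f"natural spline produced {mat.shape[1]} columns, expected {df}")
    return mat
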