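"""Natural cubic spline bases for the meteorological covariates.

A basis of ``df`` centered columns is built per covariate, with interior
knots at equally spaced quantiles of the training values and boundary
knots at the observed min/max.  "Natural" means the fitted function is
constrained to be linear at and beyond the boundary knots (second
derivative zero), which keeps extrapolation to future months sane.

The construction mirrors the usual regression-spline recipe: a cubic
B-spline design matrix is projected onto the null space of the two
boundary second-derivative constraints (via a QR factorization), and the
leading B-spline column is dropped so the basis carries no intercept.
Column means over the training sample are subtracted and frozen so the
same basis can be re-evaluated at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class SplineBasisDef:
    """Frozen definition of a fitted natural cubic spline basis."""

    df: int
    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    centering: np.ndarray          # per-column training means
    projection: np.ndarray         # (n_bsplines-1) x df null-space map

    def __post_init__(self) -> None:
        self.interior_knots = np.asarray(self.interior_knots, dtype=float)
        self.centering = np.asarray(self.centering, dtype=float)
        self.projection = np.asarray(self.projection, dtype=float)
        lo, hi = self.boundary_knots
        if self.interior_knots.size and not (
                lo < self.interior_knots.min()
                and self.interior_knots.max() < hi):
            raise ValueError("interior knots must lie strictly inside the boundary")

    @property
    def full_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.concatenate([[lo] * 4, self.interior_knots, [hi] * 4])

    def to_dict(self) -> dict:
        return {
            "df": int(self.df),
            "interior_knots": self.interior_knots.tolist(),
            "boundary_knots": [float(b) for b in self.boundary_knots],
            "centering": self.centering.tolist(),
            "projection": self.projection.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasisDef":
        return cls(df=d["df"],
                   interior_knots=np.asarray(d["interior_knots"]),
                   boundary_knots=tuple(d["boundary_knots"]),
                   centering=np.asarray(d["centering"]),
                   projection=np.asarray(d["projection"]))


def _bspline_design(knots: np.ndarray, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Dense cubic B-spline design matrix (all basis functions, order 4)."""
    n_basis = len(knots) - 4
    out = np.empty((x.size, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        b = BSpline(knots, c, 3, extrapolate=False)
        if deriv:
            b = b.derivative(deriv)
        vals = b(x)
        # values exactly at the right boundary need the closed interval
        out[:, j] = np.nan_to_num(vals, nan=0.0)
    # fix right-boundary evaluation (BSpline is right-open)
    hi = knots[-1]
    at_hi = x == hi
    if np.any(at_hi):
        eps = 1e-9 * max(1.0, abs(hi))
        out[at_hi] = _bspline_design(knots, np.array([hi - eps]), deriv)[0]
    return out


def fit_basis(x: np.ndarray, df: int) -> tuple[SplineBasisDef, np.ndarray]:
    """Fit a centered natural cubic spline basis with ``df`` columns.

    Interior knots sit at the ``i/df`` quantiles (i = 1..df-1) of ``x``;
    boundary knots at min/max.  Returns the frozen definition and the
    ``n x df`` training design matrix.
    """
    x = np.asarray(x, dtype=float).ravel()
    if df < 1:
        raise ValueError("df must be >= 1")
    if x.size <= df:
        raise ValueError("need more observations than degrees of freedom")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("covariate is constant; spline basis undefined")
    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs)
    if np.any(interior <= lo) or np.any(interior >= hi) or (
            interior.size > 1 and np.any(np.diff(interior) <= 0)):
        raise ValueError("degenerate quantile knots (ties in covariate values)")
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])

    # second-derivative constraints at both boundaries, intercept column dropped
    const = _bspline_design(knots, np.array([lo, hi]), deriv=2)[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    projection = q[:, 2:]                      # null space of the constraints
    if projection.shape[1] != df:
        raise AssertionError("natural-spline dimension bookkeeping failed")

    basis_def = SplineBasisDef(df=df, interior_knots=interior,
                               boundary_knots=(lo, hi),
                               centering=np.zeros(df),
                               projection=projection)
    raw = _evaluate_uncentered(basis_def, x)
    basis_def.centering = raw.mean(axis=0)
    return basis_def, raw - basis_def.centering


def _evaluate_uncentered(basis_def: SplineBasisDef,
                         x: np.ndarray) -> np.ndarray:
    """Natural basis values at x, with linear extrapolation outside the
    boundary knots (first-order Taylor expansion at the boundary)."""
    x = np.asarray(x, dtype=float).ravel()
    knots = basis_def.full_knots
    lo, hi = basis_def.boundary_knots
    inside = np.clip(x, lo, hi)
    vals = _bspline_design(knots, inside)[:, 1:] @ basis_def.projection
    below, above = x < lo, x > hi
    for mask, b in ((below, lo), (above, hi)):
        if np.any(mask):
            f = _bspline_design(knots, np.array([b]))[:, 1:] @ basis_def.projection
            d = _bspline_design(knots, np.array([b]), deriv=1)[:, 1:] @ basis_def.projection
            vals[mask] = f + (x[mask] - b)[:, None] * d
    return vals


def apply_basis(basis_def: SplineBasisDef,
                x_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a fitted basis at new points (frozen knots and centering).

    Returns the design matrix and a boolean mask flagging points outside
    the boundary knots (where the basis extrapolates linearly).
    """
    x_new = np.asarray(x_new, dtype=float).ravel()
    lo, hi = basis_def.boundary_knots
    extrapolated = (x_new < lo) | (x_new > hi)
    return _evaluate_uncentered(basis_def, x_new) - basis_def.centering, extrapolated
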