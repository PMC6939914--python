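"""Penalized cubic B-spline bases for smooth terms.

Each smooth is a cubic B-spline expansion on quantile-spaced knots with a
derivative-based wiggliness penalty (integrated squared second derivative by
default, first derivative for ``penalty_order=1``).  With the second-derivative
penalty the null space contains exactly the straight lines in the covariate,
so an unpenalized component (level + trend) survives arbitrarily heavy
smoothing unless null-space shrinkage is requested.

Identifiability against model intercepts is handled by a sum-to-zero
(centering) constraint absorbed into the basis via an orthonormal
reparameterization, so a smooth with ``k`` coefficients yields ``k - 1``
design columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

_DEGREE = 3  # cubic splines throughout

#: Relative weight of the null-space shrinkage penalty for shrinkable smooths
#: (plot-level deviation smooths), as a fraction of the mean non-null
#: penalty eigenvalue.  Lets a single smoothing parameter shrink the whole
#: smooth, null space included, to zero — random-smooth-deviation behaviour.
NULLSPACE_SHRINK = 0.01


@dataclass(frozen=True)
class SmoothSpec:
    """Specification of one smooth term.

    Parameters
    ----------
    covariate
        Name of the covariate the smooth is a function of (time, in months).
    by_level
        Factor level (treatment or plot id) this smooth is switched on for,
        or ``None`` for a global smooth.
    k
        Basis dimension before the centering constraint.
    penalty_order
        1 or 2: order of the derivative whose integrated square is penalized.
    shrink_nullspace
        If True, the penalty is augmented so that the penalty null space is
        also shrunk toward zero (used for plot-deviation smooths).
    """

    covariate: str = "time"
    by_level: object | None = None
    k: int = 10
    penalty_order: int = 2
    shrink_nullspace: bool = False

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")
        if self.penalty_order not in (1, 2):
            raise ValueError("penalty_order must be 1 or 2")


@dataclass
class BasisBlock:
    """A constructed basis: design columns, penalty, and prediction info."""

    design_columns: np.ndarray
    penalty: np.ndarray
    null_dim: int
    knots: np.ndarray
    constraint_transform: np.ndarray | None = None
    spec: SmoothSpec | None = None
    x_range: tuple[float, float] = field(default=(0.0, 1.0))

    def predict_design(self, x_new: np.ndarray) -> np.ndarray:
        """Evaluate the (constrained) basis at new covariate values."""
        x_new = np.asarray(x_new, dtype=float)
        lo, hi = self.x_range
        if np.any(x_new < lo - 1e-9) or np.any(x_new > hi + 1e-9):
            raise ValueError("prediction points outside the fitted range")
        X = _bspline_design(np.clip(x_new, lo, hi), self.knots)
        if self.constraint_transform is not None:
            X = X @ self.constraint_transform
        return X


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Full knot vector (boundary knots repeated) for k cubic basis functions.

    Interior knots sit at quantiles of the unique covariate values.
    """
    xu = np.unique(x)
    n_interior = k - _DEGREE - 1
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(xu, probs)
    else:
        interior = np.array([])
    lo, hi = xu[0], xu[-1]
    return np.concatenate(
        [np.repeat(lo, _DEGREE + 1), interior, np.repeat(hi, _DEGREE + 1)]
    )


def _bspline_design(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    c = np.eye(len(knots) - _DEGREE - 1)
    spl = BSpline(knots, c, _DEGREE, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    X = spl(x)
    return np.nan_to_num(X, nan=0.0)


def _derivative_penalty(knots: np.ndarray, order: int) -> np.ndarray:
    """Exact integral of products of order-th basis derivatives.

    The order-th derivative of a cubic B-spline is piecewise polynomial of
    degree ``3 - order``; Gauss–Legendre with ``4 - order`` nodes per
    inter-knot interval integrates the products exactly.
    """
    k = len(knots) - _DEGREE - 1
    breaks = np.unique(knots)
    npts = 4 - order
    nodes, weights = leggauss(npts)
    S = np.zeros((k, k))
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        xm, xr = (a + b) / 2.0, (b - a) / 2.0
        xq = xm + xr * nodes
        D = _bspline_design(xq, knots, deriv=order)
        S += xr * (D * weights[:, None]).T @ D
    return (S + S.T) / 2.0


def _centering_transform(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of the column-mean constraint."""
    c = X.mean(axis=0)
    # Householder-style: full QR of c as a column, drop the first column.
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(len(c))]))
    Z = q[:, 1 : len(c)]
    return Z


def build_basis(x: np.ndarray, spec: SmoothSpec, center: bool = True) -> BasisBlock:
    """Construct the penalized-spline design and penalty for one smooth.

    Parameters
    ----------
    x
        Covariate values at the data points (need not be sorted).
    spec
        Smooth specification.
    center
        Absorb the sum-to-zero constraint (default) so the smooth is
        identifiable next to an intercept; yields ``k - 1`` columns.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < spec.k:
        raise ValueError(
            f"need at least k={spec.k} distinct covariate values, "
            f"got {np.unique(x).size}"
        )
    knots = _quantile_knots(x, spec.k)
    X = _bspline_design(x, knots)
    S = _derivative_penalty(knots, spec.penalty_order)
    null_dim = spec.penalty_order

    Z = None
    if center:
        Z = _centering_transform(X)
        X = X @ Z
        S = Z.T @ S @ Z
        null_dim = max(null_dim - 1, 0)

    if spec.shrink_nullspace and null_dim > 0:
        w, U = np.linalg.eigh(S)
        tol = max(w.max(), 1.0) * 1e-10
        null_vecs = U[:, w < tol]
        scale = w[w >= tol].mean() if np.any(w >= tol) else 1.0
        S = S + NULLSPACE_SHRINK * scale * (null_vecs @ null_vecs.T)
        null_dim = 0

    return BasisBlock(
        design_columns=X,
        penalty=(S + S.T) / 2.0,
        null_dim=null_dim,
        knots=knots,
        constraint_transform=Z,
        spec=spec,
        x_range=(float(np.min(x)), float(np.max(x))),
    )
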