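"""Penalized-spline GAMs with treatment-specific and plot-specific smooths.

The model for a count or flux series is

    g(E[y_it]) = a_{tr(i)} + f_{tr(i)}(t) + g_i(t)

with g the log link, a treatment-level intercept per pre-intervention
treatment group, f a treatment-specific smooth of time, and g_i a small
plot-specific deviation smooth whose whole span (null space included) is
shrunk toward zero, so plots behave as smooth random departures from their
treatment curve.  Families: Poisson (counts) and Tweedie with
1 < power < 2 (non-negative continuous flux with exact zeros); a Gaussian
family with identity link is provided for validation against least squares.

Fitting is penalized IRLS.  Smoothing parameters are chosen by GCV,
minimized coordinate-wise by Brent search on log(lambda) inside a
performance-iteration outer loop (the working penalized least-squares
problem is re-smoothed at each outer step).  The posterior covariance of
the coefficients is the usual Bayesian one,
V = (X'WX + sum_j lambda_j S_j)^-1 * phi, which is what the
difference-of-smooths credible intervals are built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .basis import BasisBlock, SmoothSpec, build_basis

logger = logging.getLogger(__name__)

LOG_LAMBDA_BOUNDS = (-6.0, 9.0)  # log10 search range for smoothing parameters


class FitError(RuntimeError):
    """Raised when penalized IRLS fails to converge; carries the trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Families


class Family:
    """Exponential-family variance/deviance bundle with a log or identity link."""

    name = "base"
    link = "log"
    fixed_scale: float | None = None

    def variance(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        raise NotImplementedError

    def initial_mu(self, y: np.ndarray) -> np.ndarray:
        return np.maximum(y, 0) + 0.5


class Poisson(Family):
    name = "poisson"
    fixed_scale = 1.0

    def variance(self, mu):
        return mu

    def deviance(self, y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))


class Tweedie(Family):
    """Compound Poisson–gamma family: Var(y) = phi * mu^p, 1 < p < 2."""

    name = "tweedie"

    def __init__(self, power: float = 1.5):
        if not 1.0 < power < 2.0:
            raise ValueError("tweedie power must lie strictly between 1 and 2")
        self.power = power

    def variance(self, mu):
        return mu**self.power

    def deviance(self, y, mu):
        p = self.power
        d = (
            np.maximum(y, 0) ** (2 - p) / ((1 - p) * (2 - p))
            - y * mu ** (1 - p) / (1 - p)
            + mu ** (2 - p) / (2 - p)
        )
        return float(2.0 * np.sum(d))


class Gaussian(Family):
    name = "gaussian"
    link = "identity"

    def variance(self, mu):
        return np.ones_like(mu)

    def deviance(self, y, mu):
        return float(np.sum((y - mu) ** 2))

    def initial_mu(self, y):
        return y.astype(float)


def make_family(name: str, tweedie_power: float = 1.5) -> Family:
    name = name.lower()
    if name == "poisson":
        return Poisson()
    if name == "tweedie":
        return Tweedie(tweedie_power)
    if name == "gaussian":
        return Gaussian()
    raise ValueError(f"unknown family {name!r}")


# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: family and smooth structure.

    The design always contains one intercept per treatment level and one
    centered smooth of time per treatment level.  Plot-deviation smooths
    (one per plot, sharing a single smoothing parameter, null space shrunk)
    are added when ``plot_smooths`` is True and the data carry a plot column.
    """

    family: str = "poisson"
    tweedie_power: float = 1.5
    k_treatment: int = 20
    k_plot: int = 8
    plot_smooths: bool = True
    penalty_order: int = 2
    # shrink the penalty null space of every smooth so that a no-signal fit
    # can reach edf ~ 0 (plot smooths always shrink regardless)
    shrink_nullspace: bool = True


@dataclass
class FitControl:
    """Convergence and smoothing-selection settings."""

    tol: float = 1e-8
    max_iter: int = 200
    max_outer: int = 10
    select: str = "gcv"  # "gcv" or "fixed"
    fixed_lambda: dict[str, float] | float | None = None
    # gamma > 1 inflates the effective-dof cost in GCV, the standard remedy
    # for GCV's tendency to undersmooth
    gcv_gamma: float = 1.4


@dataclass
class _Block:
    """Internal: one column block of the design."""

    name: str
    cols: slice
    basis: BasisBlock | None = None
    group: str | None = None  # penalty group name (None = unpenalized)
    level: object | None = None  # treatment or plot level switching it on


@dataclass
class FittedGAM:
    beta: np.ndarray
    V_beta: np.ndarray
    lambda_: dict[str, float]
    phi: float
    edf: dict[str, float]
    deviance: float
    family: Family = dc_field(repr=False, default=None)
    blocks: list[_Block] = dc_field(repr=False, default_factory=list)
    treatment_levels: list = dc_field(default_factory=list)
    plot_levels: list = dc_field(default_factory=list)
    time_range: tuple[float, float] = (0.0, 1.0)
    n_obs: int = 0
    degenerate: bool = False
    spec: ModelSpec | None = None

    @property
    def edf_total(self) -> float:
        return float(sum(self.edf.values()))


# ---------------------------------------------------------------------------
# Design construction


def _build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[_Block], dict[str, list[tuple[slice, np.ndarray]]], list, list]:
    t = np.asarray(data["time"], dtype=float)
    n = len(data)
    treatments = (
        sorted(pd.unique(data["treatment"]))
        if "treatment" in data.columns
        else ["all"]
    )
    tr = (
        np.asarray(data["treatment"])
        if "treatment" in data.columns
        else np.repeat("all", n)
    )
    plots = (
        sorted(pd.unique(data["plot"]))
        if (spec.plot_smooths and "plot" in data.columns)
        else []
    )

    cols: list[np.ndarray] = []
    blocks: list[_Block] = []
    penalties: dict[str, list[tuple[slice, np.ndarray]]] = {}
    pos = 0

    # treatment intercepts (no global intercept)
    for lev in treatments:
        cols.append((tr == lev).astype(float)[:, None])
        blocks.append(_Block(name=f"intercept:{lev}", cols=slice(pos, pos + 1)))
        pos += 1

    # treatment-specific smooths of time
    treat_design: dict = {}
    for lev in treatments:
        mask = tr == lev
        bb = build_basis(
            t[mask],
            SmoothSpec(
                covariate="time", by_level=lev, k=spec.k_treatment,
                penalty_order=spec.penalty_order,
                shrink_nullspace=spec.shrink_nullspace,
            ),
        )
        Xs = np.zeros((n, bb.design_columns.shape[1]))
        Xs[mask] = bb.design_columns
        sl = slice(pos, pos + Xs.shape[1])
        cols.append(Xs)
        gname = f"s(time):{lev}"
        blocks.append(_Block(name=gname, cols=sl, basis=bb, group=gname, level=lev))
        penalties[gname] = [(sl, bb.penalty)]
        treat_design[lev] = Xs
        pos += Xs.shape[1]

    # plot-deviation smooths, one shared smoothing parameter.  Each plot's
    # columns are residualized against [intercept, treatment smooth basis]
    # on that plot's rows, so a treatment-level signal is identifiable to
    # the treatment smooth only and cannot migrate into the deviations.
    if plots:
        plot_arr = np.asarray(data["plot"])
        penalties["s(time):plots"] = []
        for p in plots:
            mask = plot_arr == p
            lev = tr[mask][0]
            bb = build_basis(
                t[mask],
                SmoothSpec(
                    covariate="time", by_level=p, k=spec.k_plot,
                    penalty_order=spec.penalty_order, shrink_nullspace=True,
                ),
            )
            local = bb.design_columns
            A = np.column_stack(
                [np.ones(mask.sum()), treat_design[lev][mask]]
            )
            coef, *_ = np.linalg.lstsq(A, local, rcond=None)
            local = local - A @ coef
            Xs = np.zeros((n, local.shape[1]))
            Xs[mask] = local
            sl = slice(pos, pos + Xs.shape[1])
            cols.append(Xs)
            blocks.append(
                _Block(
                    name=f"s(time):plot:{p}", cols=sl, basis=bb,
                    group="s(time):plots", level=p,
                )
            )
            penalties["s(time):plots"].append((sl, bb.penalty))
            pos += Xs.shape[1]

    X = np.concatenate(cols, axis=1)
    return X, blocks, penalties, treatments, plots


def _penalty_matrix(
    penalties: dict[str, list[tuple[slice, np.ndarray]]],
    lam: dict[str, float],
    p: int,
) -> np.ndarray:
    S = np.zeros((p, p))
    for g, parts in penalties.items():
        for sl, Sj in parts:
            S[sl, sl] += lam[g] * Sj
    return S


# ---------------------------------------------------------------------------
# Penalized IRLS and GCV smoothing selection


def _pls_solve(XtWX, XtWz, S):
    A = XtWX + S
    # small ridge keeps the Cholesky stable when lambda -> 0 on a rank-
    # deficient working design
    jitter = 1e-10 * (np.trace(A) / A.shape[0] + 1.0)
    c = cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
    return cho_solve(c, XtWz), c


def _gcv_score(XtWX, XtWz, zWz, S, n, gamma):
    beta, c = _pls_solve(XtWX, XtWz, S)
    # tr(A) = tr[(X'WX + S)^-1 X'WX]
    tr = float(np.trace(cho_solve(c, XtWX)))
    rss = float(zWz - 2 * beta @ XtWz + beta @ XtWX @ beta)
    denom = max(n - gamma * tr, 1e-3)
    return n * max(rss, 1e-300) / denom**2


def _select_lambda(XtWX, XtWz, zWz, penalties, lam, n, gamma, p):
    """Coordinate-wise Brent minimization of GCV over log10(lambda)."""
    for _ in range(2):
        for g in penalties:
            def score(loglam, g=g):
                trial = dict(lam)
                trial[g] = 10.0**loglam
                S = _penalty_matrix(penalties, trial, p)
                return _gcv_score(XtWX, XtWz, zWz, S, n, gamma)

            res = minimize_scalar(
                score, bounds=LOG_LAMBDA_BOUNDS, method="bounded",
                options={"xatol": 1e-2},
            )
            lam[g] = 10.0 ** float(res.x)
    return lam


def fit_gam(
    data: pd.DataFrame,
    model: ModelSpec | None = None,
    control: FitControl | None = None,
) -> FittedGAM:
    """Fit a penalized GAM to a (response, time, treatment, plot) table.

    Parameters
    ----------
    data
        Must contain ``response`` and ``time``; ``treatment`` and ``plot``
        columns are used when present (treatment-specific smooths, plot
        deviation smooths).
    model
        Family and smooth structure; defaults to a Poisson model.
    control
        Fitting tolerances and the smoothing-parameter selection method.
        ``select="fixed"`` with ``fixed_lambda`` skips GCV (a scalar is
        broadcast to every penalty group; 0 gives an unpenalized fit).
    """
    model = model or ModelSpec()
    control = control or FitControl()
    fam = make_family(model.family, model.tweedie_power)

    y = np.asarray(data["response"], dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    n = len(y)

    X, blocks, penalties, treatments, plots = _build_design(data, model)
    p = X.shape[1]

    degenerate = bool(np.all(y == 0))
    if degenerate:
        logger.warning("all-zero response: degenerate fit flagged")

    # initial smoothing parameters
    if control.select == "fixed":
        if isinstance(control.fixed_lambda, dict):
            lam = {g: float(control.fixed_lambda.get(g, 0.0)) for g in penalties}
        else:
            lam = {g: float(control.fixed_lambda or 0.0) for g in penalties}
    else:
        # start treatment smooths flexible and plot deviations heavily
        # shrunk, so treatment-level signal is claimed by the treatment
        # smooths rather than absorbed into the plot deviations (the
        # coordinate-wise GCV search is order dependent otherwise)
        lam = {
            g: (1e6 if g == "s(time):plots" else 1e-2) for g in penalties
        }

    mu = np.maximum(fam.initial_mu(y), 1e-8)
    eta = np.log(mu) if fam.link == "log" else mu
    dev = fam.deviance(y, mu)
    trace = [dev]

    def pirls(lam):
        nonlocal mu, eta, dev
        for it in range(control.max_iter):
            if fam.link == "log":
                w = np.maximum(mu**2 / np.maximum(fam.variance(mu), 1e-12), 1e-12)
                z = eta + (y - mu) / np.maximum(mu, 1e-12)
            else:
                w = 1.0 / np.maximum(fam.variance(mu), 1e-12)
                z = y
            Xw = X * w[:, None]
            XtWX = X.T @ Xw
            XtWz = Xw.T @ z
            S = _penalty_matrix(penalties, lam, p)
            beta, chol = _pls_solve(XtWX, XtWz, S)
            eta = np.clip(X @ beta, -30, 30)
            mu = np.exp(eta) if fam.link == "log" else eta
            mu = np.maximum(mu, 1e-12) if fam.link == "log" else mu
            dev_new = fam.deviance(y, mu)
            trace.append(dev_new)
            done = abs(dev_new - dev) < control.tol * (abs(dev) + 0.1)
            dev = dev_new
            if done:
                return beta, w, z, XtWX, XtWz
        raise FitError(
            f"penalized IRLS did not converge in {control.max_iter} iterations",
            trace,
        )

    outer_range = range(control.max_outer) if control.select == "gcv" else range(1)
    best_lam, best_gcv = dict(lam), np.inf

    for outer in outer_range:
        lam_old = dict(lam)
        beta, w, z, XtWX, XtWz = pirls(lam)

        if control.select != "gcv" or not penalties:
            break
        # performance iteration: re-select lambda on the working model.
        # The coordinate search can wander between local optima (e.g.
        # treatment signal migrating into the plot-deviation smooths), so
        # keep the best state seen by its own GCV score.
        zWz = float(np.sum(w * z * z))
        if outer > 0:  # skip the deliberately undersmoothed starting state
            S_cur = _penalty_matrix(penalties, lam, p)
            gcv_cur = _gcv_score(XtWX, XtWz, zWz, S_cur, n, control.gcv_gamma)
            if gcv_cur < best_gcv:
                best_gcv, best_lam = gcv_cur, dict(lam)
        lam = _select_lambda(
            XtWX, XtWz, zWz, penalties, lam, n, control.gcv_gamma, p
        )
        rel = max(
            (abs(np.log10(lam[g] + 1e-300) - np.log10(lam_old[g] + 1e-300)))
            for g in lam
        )
        if rel < 0.05 and outer > 0:
            break

    if control.select == "gcv" and penalties:
        lam = best_lam
        beta, w, z, XtWX, XtWz = pirls(lam)

    # final quantities at the converged fit
    if fam.link == "log":
        w = np.maximum(mu**2 / np.maximum(fam.variance(mu), 1e-12), 1e-12)
    else:
        w = 1.0 / np.maximum(fam.variance(mu), 1e-12)
    XtWX = (X * w[:, None]).T @ X
    S = _penalty_matrix(penalties, lam, p)
    _, chol = _pls_solve(XtWX, np.zeros(p), S)
    Ainv = cho_solve(chol, np.eye(p))
    F = Ainv @ XtWX  # edf matrix

    edf: dict[str, float] = {}
    for b in blocks:
        if b.group is not None:
            edf[b.name] = float(np.trace(F[b.cols, b.cols]))
    edf_total = float(np.trace(F))

    if fam.fixed_scale is not None:
        phi = fam.fixed_scale
    else:
        pearson = float(np.sum((y - mu) ** 2 / np.maximum(fam.variance(mu), 1e-12)))
        phi = pearson / max(n - edf_total, 1.0)

    V = Ainv * phi
    V = (V + V.T) / 2.0

    return FittedGAM(
        beta=beta,
        V_beta=V,
        lambda_=lam,
        phi=phi,
        edf=edf,
        deviance=dev,
        family=fam,
        blocks=blocks,
        treatment_levels=list(treatments),
        plot_levels=list(plots),
        time_range=(float(np.min(data["time"])), float(np.max(data["time"]))),
        n_obs=n,
        degenerate=degenerate,
        spec=model,
    )


# ---------------------------------------------------------------------------
# Prediction


def prediction_rows(
    fit: FittedGAM,
    treatment,
    grid: np.ndarray,
    include_plot_effects: bool = False,
) -> np.ndarray:
    """Design rows mapping coefficients to the treatment curve on a grid.

    Rows contain the treatment intercept and the treatment smooth; plot
    deviation columns are zero unless ``include_plot_effects``, in which
    case the average of the plot deviation curves is added.
    """
    if treatment not in fit.treatment_levels:
        raise KeyError(f"unknown treatment level {treatment!r}")
    grid = np.asarray(grid, dtype=float)
    p = len(fit.beta)
    C = np.zeros((len(grid), p))
    for b in fit.blocks:
        if b.name == f"intercept:{treatment}":
            C[:, b.cols] = 1.0
        elif b.group == f"s(time):{treatment}":
            C[:, b.cols] = b.basis.predict_design(grid)
        elif include_plot_effects and b.group == "s(time):plots":
            C[:, b.cols] = b.basis.predict_design(grid) / max(len(fit.plot_levels), 1)
    return C


def predict_treatment_curve(
    fit: FittedGAM,
    treatment,
    grid: np.ndarray,
    include_plot_effects: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Treatment curve on the link scale with pointwise standard errors."""
    lo, hi = fit.time_range
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < lo - 1e-9) or np.any(grid > hi + 1e-9):
        raise ValueError("grid outside the fitted time range")
    C = prediction_rows(fit, treatment, grid, include_plot_effects)
    est = C @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, fit.V_beta, C), 0.0))
    return est, se
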