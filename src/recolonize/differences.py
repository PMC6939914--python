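"""Difference-of-smooths credible intervals and convergence-time detection.

Treatment effects are read off the fitted GAM as the link-scale difference
between two treatment curves.  Because the difference is a linear functional
c'beta of the coefficients, a credible interval follows directly from the
Bayesian posterior beta ~ N(beta_hat, V_beta): pointwise bounds use the
normal quantile; simultaneous bounds use the max-|t| criterion over
posterior draws.  A treatment is declared converged with the reference once
the credible interval contains zero and keeps containing it for a required
sustained run of months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .gam import FittedGAM, prediction_rows

DEFAULT_POSTERIOR_DRAWS = 10_000


@dataclass
class DifferenceCurve:
    """Link-scale difference between two treatment smooths on a time grid."""

    grid: np.ndarray
    diff: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    simultaneous: bool = False
    treatments: tuple = ("A", "B")

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        for name in ("diff", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lower > self.diff + 1e-12) or np.any(
            self.upper < self.diff - 1e-12
        ):
            raise ValueError("bounds must bracket the estimate")

    def contains_zero(self) -> np.ndarray:
        return (self.lower <= 0.0) & (self.upper >= 0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.grid,
                "diff": self.diff,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class ConvergenceReport:
    """When (if ever) a difference curve becomes indistinguishable from zero."""

    converge_month: float | None
    months_since_change: float | None
    excursions: list[tuple[float, float]] = field(default_factory=list)
    intervention: float = 0.0


def difference_smooth(
    fit: FittedGAM,
    treat_a,
    treat_b,
    grid: np.ndarray,
    level: float = 0.95,
    simultaneous: bool = False,
    n_draws: int = DEFAULT_POSTERIOR_DRAWS,
    seed: int | None = 0,
) -> DifferenceCurve:
    """Credible band for the link-scale difference of two treatment curves.

    The contrast rows exclude plot-deviation columns, so the difference is
    between the treatment-level mean curves (intercepts included).  With
    ``simultaneous=True`` the band has joint coverage over the whole grid,
    built from the max-|t| statistic across posterior draws of beta.
    """
    grid = np.asarray(grid, dtype=float)
    Ca = prediction_rows(fit, treat_a, grid)
    Cb = prediction_rows(fit, treat_b, grid)
    C = Ca - Cb
    diff = C @ fit.beta
    var = np.maximum(np.einsum("ij,jk,ik->i", C, fit.V_beta, C), 0.0)
    se = np.sqrt(var)

    if treat_a == treat_b:
        zero = np.zeros_like(grid)
        return DifferenceCurve(
            grid, zero, zero.copy(), zero.copy(), level, simultaneous,
            (treat_a, treat_b),
        )

    if not simultaneous:
        zq = norm.ppf(0.5 + level / 2.0)
        crit = zq
    else:
        rng = np.random.default_rng(seed)
        # draws of c'beta via the covariance of the contrast values
        CV = C @ fit.V_beta @ C.T
        CV = (CV + CV.T) / 2.0
        L = np.linalg.cholesky(CV + 1e-12 * np.eye(len(grid)))
        draws = rng.standard_normal((n_draws, len(grid))) @ L.T
        with np.errstate(invalid="ignore", divide="ignore"):
            tmax = np.nanmax(np.abs(draws) / np.where(se > 0, se, np.nan), axis=1)
        crit = float(np.quantile(tmax, level))
        crit = max(crit, norm.ppf(0.5 + level / 2.0))

    return DifferenceCurve(
        grid, diff, diff - crit * se, diff + crit * se, level, simultaneous,
        (treat_a, treat_b),
    )


def detect_convergence(
    curve: DifferenceCurve,
    intervention: float,
    sustain: float | None = None,
) -> ConvergenceReport:
    """Earliest post-intervention time from which the band contains zero.

    Parameters
    ----------
    curve
        The difference curve to scan.
    intervention
        Time of the treatment change; only grid points at or after it are
        considered.
    sustain
        Minimum run of months the interval must keep containing zero from
        the candidate time onward.  ``None`` (default) requires inclusion
        through the end of the series; later zero-exclusions are then
        impossible by construction.  With a finite sustain, post-convergence
        intervals where zero is excluded are reported as excursions rather
        than resetting the convergence time.
    """
    grid = curve.grid
    if intervention < grid[0] - 1e-9 or intervention > grid[-1] + 1e-9:
        raise ValueError("intervention time outside the grid range")
    inside = curve.contains_zero()
    post = grid >= intervention - 1e-9
    idx_post = np.nonzero(post)[0]

    converge_idx: int | None = None
    for i in idx_post:
        if not inside[i]:
            continue
        horizon = grid[i] + (np.inf if sustain is None else sustain)
        window = (grid >= grid[i]) & (grid <= horizon)
        if inside[window].all():
            converge_idx = i
            break

    if converge_idx is None:
        return ConvergenceReport(None, None, [], intervention)

    # excursions: contiguous post-convergence runs where zero is excluded
    excursions: list[tuple[float, float]] = []
    run_start = None
    for i in range(converge_idx, len(grid)):
        if not inside[i] and run_start is None:
            run_start = grid[i]
        elif inside[i] and run_start is not None:
            excursions.append((run_start, grid[i - 1]))
            run_start = None
    if run_start is not None:
        excursions.append((run_start, grid[-1]))

    t_star = float(grid[converge_idx])
    return ConvergenceReport(t_star, t_star - intervention, excursions, intervention)
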