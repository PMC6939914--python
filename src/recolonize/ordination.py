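"""Partial canonical correspondence analysis (pCCA) with permutation tests.

Community composition (samples x species counts) is analysed on the
chi-square standardized scale of correspondence analysis.  A conditioning
factor (year) is removed first by weighted projection onto its indicator
design; the constraint factor (treatment) is then projected onto the
residual, giving the inertia decomposition

    total = conditional (year) + constrained (treatment | year) + residual.

R^2 is reported as constrained / total inertia.  Significance of the
constraint comes from a permutation test of the pseudo-F statistic, with
the conditioning model re-projected for every permutation; free
permutation of samples is the default and a within-year restricted scheme
is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """Raised when the community table carries no chi-square inertia."""


class AliasedConstraintError(ValueError):
    """Raised when the constraint is collinear with the condition."""


@dataclass
class AbundanceTable:
    """Sample factors plus a non-negative sample x species abundance matrix."""

    samples: pd.DataFrame
    Y: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.Y):
            raise ValueError("samples and Y must have the same number of rows")
        if self.Y.shape[1] < 2:
            raise ValueError("need at least 2 species")
        if (self.Y.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    def drop_empty(self) -> "AbundanceTable":
        """Remove all-zero sample rows and species columns (logged)."""
        rows = self.Y.sum(axis=1) > 0
        cols = self.Y.sum(axis=0) > 0
        if (~rows).any():
            logger.info("dropping %d empty samples", int((~rows).sum()))
        if (~cols).any():
            logger.info("dropping %d empty species", int((~cols).sum()))
        return AbundanceTable(
            self.samples.loc[rows.values].reset_index(drop=True),
            self.Y.loc[rows.values, cols.values].reset_index(drop=True),
        )


@dataclass
class PCCAResult:
    total_inertia: float
    conditional_inertia: float
    constrained_inertia: float
    R2: float
    pseudo_F: float
    df_constraint: int
    df_residual: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    site_scores: pd.DataFrame | None = None
    perm_p: float | None = None
    n_perm: int = 0

    @property
    def residual_inertia(self) -> float:
        return self.total_inertia - self.conditional_inertia - self.constrained_inertia


def sqrt_transform(Y: pd.DataFrame | np.ndarray):
    """Element-wise square root of a non-negative abundance table."""
    arr = Y.to_numpy() if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    out = np.sqrt(arr)
    if isinstance(Y, pd.DataFrame):
        return pd.DataFrame(out, index=Y.index, columns=Y.columns)
    return out


def _dummies(factor: pd.Series, weights: np.ndarray) -> np.ndarray:
    """Weight-centered indicator design for one factor."""
    Z = pd.get_dummies(factor.astype("category")).to_numpy(dtype=float)
    Z = Z - weights @ Z  # centering w.r.t. row masses
    return Z


def _projector(Xw: np.ndarray, tol: float = 1e-10):
    """Orthonormal column basis (rank-revealing) of a weighted design."""
    if Xw.size == 0:
        return np.zeros((Xw.shape[0], 0)), 0
    U, s, _ = np.linalg.svd(Xw, full_matrices=False)
    rank = int(np.sum(s > tol * max(s[0], 1.0)))
    return U[:, :rank], rank


def _chi_square_standardize(Y: np.ndarray):
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        Qbar = (P - E) / np.sqrt(E)
    Qbar = np.nan_to_num(Qbar)
    return Qbar, r, c


def pcca(
    table: AbundanceTable,
    constraint: str = "treatment",
    condition: str | None = "year",
) -> PCCAResult:
    """Partial CCA: inertia of the constraint after removing the condition.

    Parameters
    ----------
    table
        Community table; empty rows/columns are dropped first.  Apply
        ``sqrt_transform`` to ``table.Y`` beforehand if desired — the
        pipeline applies it exactly once.
    constraint
        Factor column of ``table.samples`` whose effect is tested.
    condition
        Factor column partialled out first, or ``None`` for plain CCA.
    """
    table = table.drop_empty()
    Y = table.Y.to_numpy(dtype=float)
    n = Y.shape[0]
    Qbar, r, c = _chi_square_standardize(Y)
    total = float(np.sum(Qbar**2))
    if total < 1e-12:
        raise DegenerateTableError("community table has zero chi-square inertia")

    sw = np.sqrt(r)[:, None]

    if condition is not None:
        Zc = _dummies(table.samples[condition], r)
        Uz, rank_z = _projector(sw * Zc)
        fit_z = Uz @ (Uz.T @ Qbar)
    else:
        Uz, rank_z = np.zeros((n, 0)), 0
        fit_z = np.zeros_like(Qbar)
    conditional = float(np.sum(fit_z**2))
    R_resid = Qbar - fit_z

    Tc = _dummies(table.samples[constraint], r)
    Xt = sw * Tc
    Xt = Xt - Uz @ (Uz.T @ Xt)  # residualize constraint on condition
    Ut, q = _projector(Xt)
    if q == 0:
        raise AliasedConstraintError(
            f"constraint {constraint!r} is collinear with condition {condition!r}"
        )
    fit_t = Ut @ (Ut.T @ R_resid)
    constrained = float(np.sum(fit_t**2))
    residual = max(total - conditional - constrained, 0.0)

    df_resid = n - 1 - q - rank_z
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    pseudo_F = (constrained / q) / (residual / df_resid) if residual > 0 else np.inf

    # constrained axes (site scores) from the SVD of the fitted matrix
    U, s, Vt = np.linalg.svd(fit_t, full_matrices=False)
    keep = s > 1e-10
    eig = (s[keep] ** 2)[:q]
    with np.errstate(divide="ignore", invalid="ignore"):
        sites = np.where(sw > 0, U[:, : len(eig)] / sw, 0.0) * s[: len(eig)]
    site_scores = pd.DataFrame(
        sites[:, : len(eig)],
        columns=[f"CCA{i+1}" for i in range(len(eig))],
        index=table.samples.index,
    )

    return PCCAResult(
        total_inertia=total,
        conditional_inertia=conditional,
        constrained_inertia=constrained,
        R2=constrained / total,
        pseudo_F=pseudo_F,
        df_constraint=q,
        df_residual=df_resid,
        eigenvalues=eig,
        site_scores=site_scores,
    )


def permutation_test(
    table: AbundanceTable,
    constraint: str = "treatment",
    condition: str | None = "year",
    n_perm: int = 199,
    seed: int = 0,
    scheme: str = "free",
) -> PCCAResult:
    """Permutation p-value for the constraint's pseudo-F.

    Sample rows of the community matrix are permuted (freely, or within
    levels of the condition for ``scheme="within_year"``); the condition is
    re-projected for every permutation.  ``perm_p`` is
    ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if scheme not in ("free", "within_year"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    obs = pcca(table, constraint, condition)
    clean = table.drop_empty()
    n = len(clean.Y)
    rng = np.random.default_rng(seed)

    if scheme == "within_year":
        if condition is None:
            raise ValueError("within_year scheme requires a condition factor")
        groups = [
            np.nonzero((clean.samples[condition] == lev).to_numpy())[0]
            for lev in clean.samples[condition].unique()
        ]
        if any(len(g) < 2 for g in groups):
            raise ValueError("within_year permutation needs >= 2 samples per year")

    count = 0
    for _ in range(n_perm):
        if scheme == "free":
            idx = rng.permutation(n)
        else:
            idx = np.arange(n)
            for g in groups:
                idx[g] = g[rng.permutation(len(g))]
        Yp = clean.Y.iloc[idx].reset_index(drop=True)
        perm_table = AbundanceTable(clean.samples, Yp)
        f_perm = pcca(perm_table, constraint, condition).pseudo_F
        if f_perm >= obs.pseudo_F - 1e-12:
            count += 1

    obs.perm_p = (1 + count) / (n_perm + 1)
    obs.n_perm = n_perm
    return obs
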