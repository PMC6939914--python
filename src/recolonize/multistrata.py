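"""Multistate (Arnason–Schwarz) capture–recapture estimation.

Individuals carry a stratum label (here: the treatment type of the plot
they were caught on).  Between monthly occasions an individual survives
with the apparent-survival probability S of its current stratum, then moves
between strata according to the row-stochastic transition table Psi, and is
detected on the next occasion with the recapture probability p of its
destination stratum.  The likelihood of a capture history, conditional on
first capture, marginalizes the latent stratum sequence by a forward
recursion with an absorbing dead/emigrated state.

Model candidates constrain S, p or Psi to be shared across strata; the
constrained Psi is a single move probability split equally among the other
strata.  Parameters live on logit / multinomial-logit scales and are
maximized by L-BFGS with seeded random restarts; standard errors come from
the inverse numerical Hessian, and candidates are ranked by AIC (ties going
to the smaller model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaptureHistory:
    """Occasion-by-occasion record for one tagged individual.

    ``occasions`` holds a stratum label for each detection and ``None`` for
    each non-detection.
    """

    tag: object
    occasions: tuple

    def __post_init__(self) -> None:
        if all(o is None for o in self.occasions):
            raise ValueError("capture history has no detections")

    @property
    def first(self) -> int:
        return next(i for i, o in enumerate(self.occasions) if o is not None)

    @property
    def strata(self) -> set:
        return {o for o in self.occasions if o is not None}


@dataclass
class MultistrataParams:
    """Stratum-labelled parameter set: survival, recapture, transitions."""

    S: dict
    p: dict
    Psi: pd.DataFrame  # rows: from-stratum, cols: to-stratum

    def __post_init__(self) -> None:
        for name, d in (("S", self.S), ("p", self.p)):
            for k, v in d.items():
                if not 0.0 < v < 1.0:
                    raise ValueError(f"{name}[{k}]={v} outside (0,1)")
        rows = self.Psi.to_numpy(dtype=float)
        if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("Psi rows must sum to 1")
        if np.any(rows < 0):
            raise ValueError("Psi entries must be non-negative")

    @property
    def strata(self) -> list:
        return list(self.Psi.index)


@dataclass
class ModelCandidate:
    """One entry of the AIC candidate set."""

    S_varies: bool = True
    p_varies: bool = False
    Psi_varies: bool = True
    n_params: int = 0
    loglik: float = np.nan
    AIC: float = np.nan
    params: MultistrataParams | None = None
    converged: bool = True
    boundary: bool = False

    def label(self) -> str:
        def tag(flag):
            return "(strata)" if flag else "(.)"

        return f"S{tag(self.S_varies)} p{tag(self.p_varies)} Psi{tag(self.Psi_varies)}"


# ---------------------------------------------------------------------------
# Encoding and the forward recursion


def _encode(histories, strata: list) -> tuple[np.ndarray, np.ndarray]:
    """Histories -> int matrix (0 = non-detection, i+1 = stratum i)."""
    index = {s: i + 1 for i, s in enumerate(strata)}
    T = len(histories[0].occasions)
    M = np.zeros((len(histories), T), dtype=np.int64)
    for r, h in enumerate(histories):
        if len(h.occasions) != T:
            raise ValueError("histories must share the same number of occasions")
        for t, o in enumerate(h.occasions):
            if o is not None:
                M[r, t] = index[o]
    first = np.array([h.first for h in histories])
    return M, first


def _loglik_matrix(
    M: np.ndarray, first: np.ndarray, S: np.ndarray, p: np.ndarray, Psi: np.ndarray
) -> np.ndarray:
    """Per-history conditional log-likelihoods, vectorized over histories.

    ``alpha[n, j]`` tracks P(observations after first capture so far, alive
    in stratum j); ``dead`` absorbs death/permanent emigration, which is
    only compatible with all-non-detection tails.
    """
    N, T = M.shape
    K = len(S)
    alpha = np.zeros((N, K))
    started = first == 0
    if started.any():
        alpha[started, M[started, 0] - 1] = 1.0
    dead = np.zeros(N)

    for t in range(1, T):
        active = first < t
        newly = first == t
        if newly.any():
            alpha[newly, M[newly, t] - 1] = 1.0
        if not active.any():
            continue
        a = alpha[active]
        d = dead[active]
        d_new = d + a @ (1.0 - S)
        a_new = (a * S[None, :]) @ Psi
        obs = M[active, t]
        det = obs > 0
        out_a = np.empty_like(a_new)
        out_d = np.empty_like(d_new)
        # detected: only the observed stratum survives, dead path impossible
        if det.any():
            rows = np.nonzero(det)[0]
            o = obs[rows] - 1
            vals = a_new[rows, o] * p[o]
            out_a[rows] = 0.0
            out_a[rows, o] = vals
            out_d[rows] = 0.0
        nd = ~det
        if nd.any():
            out_a[nd] = a_new[nd] * (1.0 - p[None, :])
            out_d[nd] = d_new[nd]
        alpha[active] = out_a
        dead[active] = out_d

    lik = alpha.sum(axis=1) + dead
    return np.log(np.maximum(lik, 1e-300))


def history_likelihood(h: CaptureHistory, params: MultistrataParams) -> float:
    """Probability of one history's post-first-capture observations.

    Conditioned on the first capture (occasion and stratum); latent strata
    are marginalized by the forward recursion.  Always in (0, 1].
    """
    strata = params.strata
    for s in h.strata:
        if s not in strata:
            raise KeyError(f"stratum {s!r} not in parameter set")
    M, first = _encode([h], strata)
    S = np.array([params.S[s] for s in strata])
    p = np.array([params.p[s] for s in strata])
    Psi = params.Psi.loc[strata, strata].to_numpy(dtype=float)
    return float(np.exp(_loglik_matrix(M, first, S, p, Psi)[0]))


# ---------------------------------------------------------------------------
# Parameter packing for constrained candidates


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _n_params(cand: ModelCandidate, K: int) -> int:
    n = (K if cand.S_varies else 1) + (K if cand.p_varies else 1)
    n += K * (K - 1) if cand.Psi_varies else 1
    return n


def _unpack(theta: np.ndarray, cand: ModelCandidate, K: int):
    i = 0
    if cand.S_varies:
        S = _sigmoid(theta[i : i + K]); i += K
    else:
        S = np.repeat(_sigmoid(theta[i]), K); i += 1
    if cand.p_varies:
        p = _sigmoid(theta[i : i + K]); i += K
    else:
        p = np.repeat(_sigmoid(theta[i]), K); i += 1
    if cand.Psi_varies:
        Psi = np.empty((K, K))
        for r in range(K):
            a = theta[i : i + K - 1]; i += K - 1
            ea = np.exp(a - np.max(np.append(a, 0.0)))
            e0 = np.exp(0.0 - np.max(np.append(a, 0.0)))
            denom = e0 + ea.sum()
            off = ea / denom
            Psi[r] = np.insert(off, r, e0 / denom) if K > 1 else 1.0
    else:
        m = _sigmoid(theta[i]); i += 1
        Psi = np.full((K, K), m / max(K - 1, 1))
        np.fill_diagonal(Psi, 1.0 - m)
    return S, p, Psi


def fit_multistrata(
    histories,
    candidate: ModelCandidate | None = None,
    start: MultistrataParams | None = None,
    strata: list | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> ModelCandidate:
    """Maximize the conditional multistate likelihood for one candidate.

    Returns the candidate with ``loglik``, ``AIC``, fitted ``params`` (with
    SE-bearing scale handled downstream) filled in.
    """
    histories = list(histories)
    if not histories:
        raise ValueError("no capture histories")
    if len(histories[0].occasions) < 2:
        raise ValueError("need at least 2 occasions")
    cand = candidate or ModelCandidate()
    if strata is None:
        strata = sorted({s for h in histories for s in h.strata})
    K = len(strata)
    M, first = _encode(histories, strata)
    nper = _n_params(cand, K)

    def nll(theta):
        S, p, Psi = _unpack(theta, cand, K)
        return -float(np.sum(_loglik_matrix(M, first, S, p, Psi)))

    rng = np.random.default_rng(seed)
    starts = []
    if start is not None:
        theta0 = _pack_from_params(start, cand, strata)
        starts.append(theta0)
    starts.append(np.zeros(nper))
    while len(starts) < n_restarts + 1:
        starts.append(rng.normal(0.0, 1.0, nper))

    best = None
    for theta0 in starts:
        res = minimize(nll, theta0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and np.linalg.norm(best.jac) > 1e-2:
        raise RuntimeError(
            f"multistate optimization failed: |grad|={np.linalg.norm(best.jac):.3g}"
        )

    S, p, Psi = _unpack(best.x, cand, K)
    boundary = bool(np.any(p < 1e-4) or np.any(p > 1 - 1e-4))
    if boundary:
        logger.warning("recapture probability at boundary: %s", p)
    eps = 1e-9
    params = MultistrataParams(
        S={s: float(np.clip(S[i], eps, 1 - eps)) for i, s in enumerate(strata)},
        p={s: float(np.clip(p[i], eps, 1 - eps)) for i, s in enumerate(strata)},
        Psi=pd.DataFrame(Psi, index=strata, columns=strata),
    )
    cand.n_params = nper
    cand.loglik = -float(best.fun)
    cand.AIC = 2.0 * nper - 2.0 * cand.loglik
    cand.params = params
    cand.converged = bool(best.success)
    cand.boundary = boundary
    return cand


def _pack_from_params(params: MultistrataParams, cand: ModelCandidate, strata):
    def logit(x):
        x = np.clip(x, 1e-9, 1 - 1e-9)
        return np.log(x / (1 - x))

    K = len(strata)
    out = []
    Svals = np.array([params.S[s] for s in strata])
    pvals = np.array([params.p[s] for s in strata])
    out.extend(logit(Svals) if cand.S_varies else [logit(Svals.mean())])
    out.extend(logit(pvals) if cand.p_varies else [logit(pvals.mean())])
    Psi = params.Psi.loc[strata, strata].to_numpy(dtype=float)
    if cand.Psi_varies:
        for r in range(K):
            diag = max(Psi[r, r], 1e-9)
            for c in range(K):
                if c != r:
                    out.append(np.log(max(Psi[r, c], 1e-9) / diag))
    else:
        out.append(logit(1.0 - np.mean(np.diag(Psi))))
    return np.array(out, dtype=float)


def select_model(candidates) -> ModelCandidate:
    """Minimum-AIC candidate; ties broken toward fewer parameters."""
    cands = list(candidates)
    if not cands:
        raise ValueError("empty candidate list")
    return min(cands, key=lambda c: (c.AIC, c.n_params))


# ---------------------------------------------------------------------------
# Influx of new individuals


def tabulate_new_individuals(
    captures: pd.DataFrame, change_month: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count first-ever captures per plot and year since the treatment change.

    Each tag contributes exactly once, at its first capture (earliest month;
    within a month the first record wins and simultaneous captures on two
    plots are logged as anomalies).  Returns the per-plot influx table and
    per-treatment yearly means (means over the plots of each treatment).
    """
    req = {"tag", "plot", "month"}
    if not req <= set(captures.columns):
        raise ValueError(f"captures need columns {sorted(req)}")
    if captures.empty:
        empty = pd.DataFrame(columns=["plot", "year_since_change", "n_new", "treatment"])
        return empty, pd.DataFrame(columns=["treatment", "year_since_change", "mean_new"])

    df = captures.sort_values("month", kind="stable").reset_index()
    firsts = df.drop_duplicates(subset="tag", keep="first")
    dup = df.merge(
        firsts[["tag", "month"]], on=["tag", "month"], how="inner"
    )
    anomalies = dup.groupby("tag")["plot"].nunique()
    n_anom = int((anomalies > 1).sum())
    if n_anom:
        logger.warning("%d tags captured on two plots in one census; first record wins", n_anom)

    firsts = firsts.copy()
    firsts["year_since_change"] = np.floor(
        (firsts["month"] - change_month) / 12.0
    ).astype(int)

    has_treat = "treatment" in captures.columns
    group_cols = ["plot", "year_since_change"] + (["treatment"] if has_treat else [])
    table = (
        firsts.groupby(group_cols, as_index=False)
        .agg(n_new=("tag", "nunique"))
        .sort_values(["year_since_change", "plot"], ignore_index=True)
    )

    if has_treat:
        # plots with zero new individuals in a year still count in the mean
        plots = captures[["plot", "treatment"]].drop_duplicates("plot")
        years = sorted(table["year_since_change"].unique())
        full = (
            plots.merge(pd.DataFrame({"year_since_change": years}), how="cross")
            .merge(table[["plot", "year_since_change", "n_new"]],
                   on=["plot", "year_since_change"], how="left")
            .fillna({"n_new": 0})
        )
        means = (
            full.groupby(["treatment", "year_since_change"], as_index=False)
            .agg(mean_new=("n_new", "mean"))
        )
    else:
        means = pd.DataFrame(columns=["treatment", "year_since_change", "mean_new"])
    return table, means


# ---------------------------------------------------------------------------
# MARK-style .inp interchange


def write_inp(histories, path, strata: list | None = None) -> None:
    """Write multistate histories as MARK .inp lines, e.g. ``A0B 1;``.

    Stratum labels are mapped to single letters A, B, C, ... in the order of
    ``strata`` (sorted by default); ``0`` marks non-detection.
    """
    histories = list(histories)
    if strata is None:
        strata = sorted({s for h in histories for s in h.strata})
    letters = {s: chr(ord("A") + i) for i, s in enumerate(strata)}
    with open(path, "w") as fh:
        fh.write("/* multistate capture histories; strata: "
                 + ", ".join(f"{letters[s]}={s}" for s in strata) + " */\n")
        for h in histories:
            line = "".join(letters[o] if o is not None else "0" for o in h.occasions)
            fh.write(f"{line} 1;\n")


def read_inp(path, strata: list | None = None):
    """Read MARK .inp multistate lines back into CaptureHistory objects.

    Without an explicit ``strata`` list, letters map to themselves.
    """
    out = []
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith("/*"):
                continue
            body = line.rstrip(";").split()
            code, count = body[0], int(body[1]) if len(body) > 1 else 1
            occ = tuple(None if ch == "0" else ch for ch in code)
            for j in range(count):
                out.append(CaptureHistory(tag=f"h{i}_{j}", occasions=occ))
    if strata is not None:
        letters = {chr(ord("A") + i): s for i, s in enumerate(strata)}
        out = [
            CaptureHistory(
                tag=h.tag,
                occasions=tuple(
                    letters[o] if o is not None else None for o in h.occasions
                ),
            )
            for h in out
        ]
    return out
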