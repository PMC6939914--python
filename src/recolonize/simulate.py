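"""Seeded generator of plot-experiment datasets with known ground truth.

The emulated experiment: 10 fenced plots in 3 treatment groups (4 long-term
controls, 3 kangaroo-rat-removal plots opened to kangaroo rats, 3 total
rodent-removal plots opened to all rodents), censused monthly over
2013–2018 (72 occasions, indexed 0–71) with the treatment change in March
2015 (month 26).  Latent per-plot count trajectories are log-linear:

    log mu_p(t) = log(control_level) + traj_{tr(p)}(t) + dev_p(t)

where the treatment trajectory is a logistic recovery from the removal
level toward the control level, delayed by a per-treatment number of
months, with an optional damped seasonal overshoot on plots that lacked
any resident community (fast, oscillatory recovery), and dev_p is a
smooth mean-zero plot-level deviation.  Counts are Poisson around mu.

Individual capture histories (for the multistate model), capture records
with body masses (for metabolic flux and influx tabulation), and plant
quadrat tables with a dominant year effect and a weak treatment effect
(for the pCCA) are generated from the same layout.  Every generator is a
pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .basis import SmoothSpec, build_basis
from .multistrata import CaptureHistory

CONTROL, KR_PLUS, RODENT_PLUS = "control", "kr_plus", "rodent_plus"
TREATMENTS = (CONTROL, KR_PLUS, RODENT_PLUS)


@dataclass(frozen=True)
class ExperimentLayout:
    """Plot/treatment assignment and census calendar."""

    plots: tuple
    treatment_of_plot: dict
    census_months: tuple
    change_month: int

    def __post_init__(self) -> None:
        months = np.asarray(self.census_months)
        if np.any(np.diff(months) <= 0):
            raise ValueError("census months must be strictly increasing")
        if not months[0] < self.change_month < months[-1]:
            raise ValueError("change_month must lie strictly inside the census range")
        counts = pd.Series(
            [self.treatment_of_plot[p] for p in self.plots]
        ).value_counts()
        if (counts < 2).any():
            raise ValueError("each treatment needs at least 2 plots")

    @property
    def treatments(self) -> list:
        return sorted(set(self.treatment_of_plot.values()))

    def plots_of(self, treatment) -> list:
        return [p for p in self.plots if self.treatment_of_plot[p] == treatment]


def default_layout(
    n_control: int = 4,
    n_kr_plus: int = 3,
    n_rodent_plus: int = 3,
    n_months: int = 72,
    change_month: int = 26,
) -> ExperimentLayout:
    """The study layout: 10 plots, 72 monthly censuses, switch at month 26.

    Month 0 is January 2013, so month 26 is March 2015.
    """
    plots = tuple(range(1, n_control + n_kr_plus + n_rodent_plus + 1))
    treatment = {}
    for i, p in enumerate(plots):
        if i < n_control:
            treatment[p] = CONTROL
        elif i < n_control + n_kr_plus:
            treatment[p] = KR_PLUS
        else:
            treatment[p] = RODENT_PLUS
    return ExperimentLayout(
        plots=plots,
        treatment_of_plot=treatment,
        census_months=tuple(range(n_months)),
        change_month=change_month,
    )


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent treatment trajectories for a count metric.

    ``control_level`` is the mean count per plot per month on controls;
    ``removal_level`` the mean while the removal treatment is in force
    (near zero for kangaroo rats on removal plots).  After the change the
    log-mean rises from the removal level to the control level along a
    logistic centred ``recovery_delay`` months post-change with rate
    ``recovery_rate``; plots without a resident community additionally
    oscillate (damped sinusoid of log-amplitude ``overshoot_amplitude``).
    """

    control_level: float = 4.0
    removal_level: dict = field(
        default_factory=lambda: {KR_PLUS: 0.2, RODENT_PLUS: 0.1}
    )
    recovery_delay: dict = field(
        default_factory=lambda: {KR_PLUS: 21.0, RODENT_PLUS: 0.0}
    )
    recovery_rate: float = 0.6
    overshoot_amplitude: float = 0.3
    overshoot_treatments: tuple = (RODENT_PLUS,)
    overshoot_period: float = 12.0
    overshoot_damping: float = 0.08
    plot_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.control_level <= 0:
            raise ValueError("control_level must be positive")
        if any(v < 0 for v in self.recovery_delay.values()):
            raise ValueError("recovery_delay must be non-negative")
        if self.plot_sd < 0:
            raise ValueError("plot_sd must be non-negative")
        if any(v <= 0 for v in self.removal_level.values()):
            raise ValueError("removal_level must be positive")


def latent_log_mean(
    t: np.ndarray, treatment: str, layout: ExperimentLayout, params: TrajectoryParams
) -> np.ndarray:
    """Treatment-level log mean count at times t (no plot deviation)."""
    t = np.asarray(t, dtype=float)
    base = np.log(params.control_level)
    if treatment == CONTROL or treatment not in params.removal_level:
        return np.full_like(t, base)
    depth = np.log(params.removal_level[treatment] / params.control_level)
    delay = params.recovery_delay[treatment]
    s = t - layout.change_month - delay
    recovery = expit(params.recovery_rate * s)
    out = base + depth * (1.0 - recovery)
    if treatment in params.overshoot_treatments and params.overshoot_amplitude > 0:
        u = np.maximum(t - layout.change_month - delay, 0.0)
        osc = (
            params.overshoot_amplitude
            * np.exp(-params.overshoot_damping * u)
            * np.sin(2.0 * np.pi * u / params.overshoot_period)
        )
        out = out + np.where(t > layout.change_month + delay, osc, 0.0)
    return out


def _plot_deviations(
    layout: ExperimentLayout, plot_sd: float, rng: np.random.Generator
) -> dict:
    """Smooth mean-zero per-plot log-scale deviations (random spline coefs)."""
    months = np.asarray(layout.census_months, dtype=float)
    if plot_sd == 0:
        return {p: np.zeros_like(months) for p in layout.plots}
    bb = build_basis(months, SmoothSpec(k=5, penalty_order=2), center=True)
    X = bb.design_columns
    scale = plot_sd / np.sqrt(np.mean(np.sum(X**2, axis=1)))
    out = {}
    for p in layout.plots:
        coef = rng.normal(0.0, scale, X.shape[1])
        out[p] = X @ coef
    return out


def simulate_counts(
    layout: ExperimentLayout, params: TrajectoryParams, seed: int
) -> pd.DataFrame:
    """Poisson plot-by-month counts around the latent treatment trajectories.

    Returns one row per plot x census month with columns
    ``plot, month, count, treatment`` (treatment = pre-change group label).
    """
    rng = np.random.default_rng(seed)
    months = np.asarray(layout.census_months, dtype=float)
    devs = _plot_deviations(layout, params.plot_sd, rng)
    rows = []
    for p in layout.plots:
        tr = layout.treatment_of_plot[p]
        logmu = latent_log_mean(months, tr, layout, params) + devs[p]
        counts = rng.poisson(np.exp(logmu))
        for m, k in zip(layout.census_months, counts):
            rows.append((p, int(m), int(k), tr))
    return pd.DataFrame(rows, columns=["plot", "month", "count", "treatment"])


# ---------------------------------------------------------------------------
# Individual-level simulations


@dataclass(frozen=True)
class IndividualSimParams:
    """Ground-truth survival/recapture/transition and body-mass parameters."""

    S_by_stratum: dict = field(
        default_factory=lambda: {CONTROL: 0.85, KR_PLUS: 0.9, RODENT_PLUS: 0.8}
    )
    p_by_stratum: dict = field(
        default_factory=lambda: {CONTROL: 0.5, KR_PLUS: 0.5, RODENT_PLUS: 0.5}
    )
    Psi: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            [[0.95, 0.01, 0.04], [0.03, 0.95, 0.02], [0.05, 0.01, 0.94]],
            index=list(TREATMENTS),
            columns=list(TREATMENTS),
        )
    )
    mass_mean_by_species: dict = field(
        default_factory=lambda: {"DM": 45.0, "DO": 52.0, "DS": 130.0,
                                 "PP": 17.0, "PB": 30.0, "PF": 8.0}
    )
    mass_sd_by_species: dict = field(
        default_factory=lambda: {"DM": 5.0, "DO": 6.0, "DS": 12.0,
                                 "PP": 2.0, "PB": 4.0, "PF": 1.2}
    )

    def __post_init__(self) -> None:
        for d in (self.S_by_stratum, self.p_by_stratum):
            for k, v in d.items():
                if not 0.0 < v < 1.0:
                    raise ValueError(f"probability {k}={v} outside (0,1)")
        rows = self.Psi.to_numpy(dtype=float)
        if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("Psi rows must sum to 1")


def simulate_histories(
    layout: ExperimentLayout,
    params: IndividualSimParams,
    n_individuals: int,
    seed: int,
    n_occasions: int | None = None,
) -> list[CaptureHistory]:
    """Simulate post-first-capture multistate histories.

    Occasions are the census months at or after the treatment change (or
    the first ``n_occasions`` of them).  Each individual enters at a
    uniform occasion and stratum and then evolves survive (S of current
    stratum) -> move (Psi row) -> detect (p of destination stratum); dead
    or emigrated individuals never reappear.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    strata = list(params.Psi.index)
    K = len(strata)
    S = np.array([params.S_by_stratum[s] for s in strata])
    p = np.array([params.p_by_stratum[s] for s in strata])
    Psi = params.Psi.to_numpy(dtype=float)

    post = [m for m in layout.census_months if m >= layout.change_month]
    T = len(post) if n_occasions is None else min(n_occasions, len(post))
    if T < 2:
        raise ValueError("need at least 2 occasions after the change")

    out = []
    for i in range(n_individuals):
        f = int(rng.integers(0, T - 1))
        cur = int(rng.integers(0, K))
        occ: list = [None] * T
        occ[f] = strata[cur]
        alive = True
        for t in range(f + 1, T):
            if not alive:
                break
            if rng.random() >= S[cur]:
                alive = False
                break
            cur = int(rng.choice(K, p=Psi[cur]))
            if rng.random() < p[cur]:
                occ[t] = strata[cur]
        out.append(CaptureHistory(tag=f"ind{i}", occasions=tuple(occ)))
    return out


def simulate_captures(
    layout: ExperimentLayout,
    params: TrajectoryParams,
    indiv: IndividualSimParams,
    seed: int,
    species_probs: dict | None = None,
    monthly_persistence: float = 0.85,
) -> pd.DataFrame:
    """Tagged capture records (period, plot, species, tag, mass in g).

    Plot-month headcounts follow the latent trajectories; tags persist
    month-to-month with probability ``monthly_persistence`` so that influx
    (first captures) and recaptures are both represented.  Species are
    drawn once per individual; body mass is lognormal around the species
    mean and fixed for the individual's lifetime.
    """
    if species_probs is None:
        species_probs = {"DM": 0.65, "DO": 0.3, "DS": 0.05}
    rng = np.random.default_rng(seed)
    months = np.asarray(layout.census_months, dtype=float)
    devs = _plot_deviations(layout, params.plot_sd, rng)
    sp_names = list(species_probs)
    sp_p = np.array([species_probs[s] for s in sp_names], dtype=float)
    sp_p = sp_p / sp_p.sum()

    rows = []
    next_tag = 0
    for plot in layout.plots:
        tr = layout.treatment_of_plot[plot]
        logmu = latent_log_mean(months, tr, layout, params) + devs[plot]
        resident: list[tuple] = []  # (tag, species, mass)
        for m, lm in zip(layout.census_months, logmu):
            n = int(rng.poisson(np.exp(lm)))
            keep = [r for r in resident if rng.random() < monthly_persistence]
            while len(keep) > n:
                keep.pop(int(rng.integers(len(keep))))
            while len(keep) < n:
                sp = sp_names[int(rng.choice(len(sp_names), p=sp_p))]
                mu, sd = indiv.mass_mean_by_species[sp], indiv.mass_sd_by_species[sp]
                sigma = np.sqrt(np.log1p((sd / mu) ** 2))
                mass = float(rng.lognormal(np.log(mu) - sigma**2 / 2, sigma))
                keep.append((f"t{next_tag}", sp, mass))
                next_tag += 1
            resident = keep
            for tag, sp, mass in resident:
                rows.append((int(m), plot, tr, sp, tag, round(mass, 2)))
    return pd.DataFrame(
        rows, columns=["month", "plot", "treatment", "species", "tag", "mass_g"]
    )


# ---------------------------------------------------------------------------
# Plant community simulation


@dataclass(frozen=True)
class PlantSimParams:
    """Plant quadrat-count generator settings.

    The year main effect dominates composition (species respond strongly
    to which year it is); the treatment effect is weak — its default size
    was calibrated by a simulation sweep so the downstream pCCA attributes
    roughly 3–5% of inertia to treatment at the default design.
    """

    n_species: int = 20
    base_abundance: float = 8.0
    year_effect_sd: float = 1.0
    treatment_effect_sd: float = 0.3
    dispersion: float = 2.0
    quadrats_per_plot: int = 16

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.year_effect_sd < 0 or self.treatment_effect_sd < 0:
            raise ValueError("effect sds must be non-negative")


def simulate_plants(
    layout: ExperimentLayout,
    params: PlantSimParams,
    years: list,
    seasons: list,
    seed: int,
) -> pd.DataFrame:
    """Quadrat x species abundance table with plot/year/season/treatment factors.

    Species log-means carry a per-(year, species) effect and a smaller
    per-(treatment, species) effect; counts are negative-binomial with the
    given dispersion.  One sample row per plot x year x season x quadrat.
    """
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    rng = np.random.default_rng(seed)
    species = [f"sp{i+1:02d}" for i in range(params.n_species)]
    base = np.log(params.base_abundance) + rng.normal(0, 0.5, params.n_species)
    treatments = layout.treatments

    rows = []
    for season in seasons:
        year_eff = rng.normal(0, params.year_effect_sd, (len(years), params.n_species))
        treat_eff = rng.normal(
            0, params.treatment_effect_sd, (len(treatments), params.n_species)
        )
        for yi, year in enumerate(years):
            for plot in layout.plots:
                tr = layout.treatment_of_plot[plot]
                ti = treatments.index(tr)
                logmu = base + year_eff[yi] + treat_eff[ti]
                mu = np.exp(logmu)
                for quad in range(params.quadrats_per_plot):
                    # negative binomial via gamma-Poisson mixture
                    lam = rng.gamma(params.dispersion, mu / params.dispersion)
                    counts = rng.poisson(lam)
                    rows.append(
                        [f"{season}-{year}-p{plot}-q{quad+1}", plot, year, season, tr]
                        + counts.tolist()
                    )
    cols = ["sample", "plot", "year", "season", "treatment"] + species
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Seed splitting and ground-truth sidecar


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def ground_truth_sidecar(
    layout: ExperimentLayout,
    traj: TrajectoryParams,
    indiv: IndividualSimParams,
    plants: PlantSimParams,
    seed: int,
    path,
) -> None:
    """Echo every generator parameter to a YAML sidecar next to the data."""
    doc = {
        "seed": int(seed),
        "layout": {
            "plots": list(layout.plots),
            "treatment_of_plot": {str(k): v for k, v in layout.treatment_of_plot.items()},
            "change_month": int(layout.change_month),
            "n_months": len(layout.census_months),
        },
        "trajectory": {
            k: (dict(v) if isinstance(v, dict) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(traj).items()
        },
        "individuals": {
            "S_by_stratum": dict(indiv.S_by_stratum),
            "p_by_stratum": dict(indiv.p_by_stratum),
            "Psi": {str(i): row.to_dict() for i, row in indiv.Psi.iterrows()},
            "mass_mean_by_species": dict(indiv.mass_mean_by_species),
            "mass_sd_by_species": dict(indiv.mass_sd_by_species),
        },
        "plants": asdict(plants),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def histories_to_frame(histories) -> pd.DataFrame:
    """Histories as a two-column table (tag, occasion-stratum string)."""
    rows = [
        (h.tag, "".join("0" if o is None else str(o) for o in h.occasions))
        for h in histories
    ]
    return pd.DataFrame(rows, columns=["tag", "history"])
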