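"""End-to-end orchestration: simulate or ingest, fit, difference, report.

The full analysis covers three GAM metrics (kangaroo-rat counts,
non-kangaroo-rat granivore counts, community metabolic flux), the
difference-of-smooths convergence reports for each treatment against the
long-term controls, the multistate survival/transition model with AIC
selection, the new-individual influx table, and the plant pCCA per season.
Every stage writes plain CSV plus a YAML run manifest; a single master
seed drives all randomness through a documented splitting scheme.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differences import detect_convergence, difference_smooth
from .energetics import community_flux
from .gam import FitControl, ModelSpec, fit_gam, predict_treatment_curve
from .multistrata import (
    ModelCandidate,
    fit_multistrata,
    select_model,
    tabulate_new_individuals,
    write_inp,
)
from .ordination import AbundanceTable, permutation_test, sqrt_transform
from .simulate import (
    CONTROL,
    KR_PLUS,
    RODENT_PLUS,
    ExperimentLayout,
    IndividualSimParams,
    PlantSimParams,
    TrajectoryParams,
    default_layout,
    ground_truth_sidecar,
    histories_to_frame,
    simulate_captures,
    simulate_counts,
    simulate_histories,
    simulate_plants,
    spawn_seeds,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricSpec:
    """GAM settings for one response metric."""

    family: str = "poisson"
    k_treatment: int = 20
    k_plot: int = 8
    tweedie_power: float = 1.5


@dataclass
class PipelineConfig:
    """Everything run_all needs; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "recolonize_run"
    change_month: int = 26
    comparisons: list = field(
        default_factory=lambda: [(CONTROL, KR_PLUS), (CONTROL, RODENT_PLUS)]
    )
    credible_level: float = 0.95
    sustain_months: float | None = 6.0
    n_perm: int = 199
    n_individuals: int = 1500
    metrics: dict = field(
        default_factory=lambda: {
            "kangaroo_rats": MetricSpec("poisson"),
            "small_granivores": MetricSpec("poisson"),
            "metabolic_flux": MetricSpec("tweedie"),
        }
    )
    plant_years: list = field(default_factory=lambda: [2008, 2012, 2013, 2014, 2015])
    plant_seasons: list = field(default_factory=lambda: ["winter", "summer"])
    # generator truth (simulation mode); None entries fall back to defaults
    kr_trajectory: TrajectoryParams | None = None
    granivore_trajectory: TrajectoryParams | None = None
    individual_params: IndividualSimParams | None = None
    plant_params: PlantSimParams | None = None

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        for key in ("kr_trajectory", "granivore_trajectory",
                    "individual_params", "plant_params"):
            if doc[key] is not None and hasattr(doc[key], "items"):
                doc[key] = {
                    k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
                    for k, v in doc[key].items()
                }
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(doc), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        metrics = {
            k: MetricSpec(**v) if isinstance(v, dict) else v
            for k, v in doc.get("metrics", {}).items()
        }
        doc["metrics"] = metrics
        doc["comparisons"] = [tuple(c) for c in doc.get("comparisons", [])]
        for key in ("kr_trajectory", "granivore_trajectory"):
            if doc.get(key):
                doc[key] = TrajectoryParams(**doc[key])
        for key in ("individual_params", "plant_params"):
            if doc.get(key) and key == "plant_params":
                doc[key] = PlantSimParams(**doc[key])
            elif doc.get(key):
                d = doc[key]
                d["Psi"] = pd.DataFrame(d["Psi"])
                doc[key] = IndividualSimParams(**d)
        return cls(**doc)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return obj


def default_granivore_trajectory() -> TrajectoryParams:
    """Small-granivore dynamics: elevated where kangaroo rats were removed,
    depressed where all rodents were removed, converging within months of
    the change."""
    return TrajectoryParams(
        control_level=5.7,
        removal_level={KR_PLUS: 7.8, RODENT_PLUS: 3.1},
        recovery_delay={KR_PLUS: 0.0, RODENT_PLUS: 0.0},
        recovery_rate=1.2,
        overshoot_amplitude=0.0,
        plot_sd=0.1,
    )


# ---------------------------------------------------------------------------
# Ingest


def ingest_captures(path) -> pd.DataFrame:
    """Load and validate a captures CSV (month, plot, species, tag, mass_g)."""
    df = pd.read_csv(path)
    required = ["month", "plot", "species", "tag", "mass_g"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"captures file missing mandatory column {col!r}")
    n0 = len(df)
    bad = df["mass_g"].notna() & (df["mass_g"] <= 0)
    if bad.any():
        logger.warning("rejecting %d rows with non-positive mass", int(bad.sum()))
        df = df[~bad]
    df = df.dropna(subset=["month", "plot", "tag"])
    if len(df) < n0:
        logger.info("dropped %d malformed capture rows", n0 - len(df))
    return df.reset_index(drop=True)


def ingest_plants(path) -> AbundanceTable:
    """Load a plant quadrat CSV (factor columns then species columns)."""
    df = pd.read_csv(path)
    factor_cols = [c for c in ("sample", "plot", "year", "season", "treatment")
                   if c in df.columns]
    if "treatment" not in factor_cols or "year" not in factor_cols:
        raise ValueError("plants file needs 'treatment' and 'year' columns")
    species_cols = [c for c in df.columns if c not in factor_cols]
    if len(species_cols) < 2:
        raise ValueError("plants file needs at least 2 species columns")
    return AbundanceTable(df[factor_cols], df[species_cols].astype(float))


def counts_to_gam_frame(counts: pd.DataFrame, value_col: str = "count") -> pd.DataFrame:
    return counts.rename(columns={value_col: "response", "month": "time"})


# ---------------------------------------------------------------------------
# Stages


def _fit_metric(
    name: str,
    data: pd.DataFrame,
    mspec: MetricSpec,
    cfg: PipelineConfig,
    out: Path,
) -> dict:
    model = ModelSpec(
        family=mspec.family,
        tweedie_power=mspec.tweedie_power,
        k_treatment=mspec.k_treatment,
        k_plot=mspec.k_plot,
    )
    fit = fit_gam(data, model, FitControl())
    grid = np.arange(data["time"].min(), data["time"].max() + 1.0)
    curves = []
    for tr in fit.treatment_levels:
        est, se = predict_treatment_curve(fit, tr, grid)
        curves.append(pd.DataFrame(
            {"metric": name, "treatment": tr, "time": grid,
             "estimate": est, "se": se}))
    pd.concat(curves).to_csv(out / f"{name}_curves.csv", index=False)

    summary = {
        "metric": name, "family": mspec.family, "deviance": fit.deviance,
        "phi": fit.phi, "edf": {k: round(v, 3) for k, v in fit.edf.items()},
        "lambda": {k: float(v) for k, v in fit.lambda_.items()},
    }
    reports = {}
    post_grid = grid[grid >= cfg.change_month]
    for ref, tr in cfg.comparisons:
        curve = difference_smooth(fit, ref, tr, post_grid, level=cfg.credible_level)
        curve.to_frame().to_csv(out / f"{name}_diff_{ref}_vs_{tr}.csv", index=False)
        rep = detect_convergence(curve, cfg.change_month, sustain=cfg.sustain_months)
        reports[f"{ref}_vs_{tr}"] = {
            "converge_month": rep.converge_month,
            "months_since_change": rep.months_since_change,
            "excursions": [list(e) for e in rep.excursions],
        }
    return {"summary": summary, "convergence": reports}


def run_all(config: PipelineConfig) -> dict:
    """Run the full synthetic-data analysis; returns the report bundle.

    Outputs land under ``config.out_dir``: per-metric fitted-curve and
    difference CSVs with convergence reports, the influx table, the
    multistate AIC table and estimates, pCCA results per season, the
    ground-truth sidecar and a run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, 6)
    layout = default_layout(change_month=config.change_month)
    kr_traj = config.kr_trajectory or TrajectoryParams()
    gr_traj = config.granivore_trajectory or default_granivore_trajectory()
    indiv = config.individual_params or IndividualSimParams()
    plant_par = config.plant_params or PlantSimParams()

    bundle: dict = {"stages": []}
    stage = "simulate"
    try:
        kr_counts = simulate_counts(layout, kr_traj, seeds[0])
        gr_counts = simulate_counts(layout, gr_traj, seeds[1])
        captures = simulate_captures(layout, kr_traj, indiv, seeds[2])
        histories = simulate_histories(
            layout, indiv, config.n_individuals, seeds[3]
        )
        plants = simulate_plants(
            layout, plant_par, config.plant_years, config.plant_seasons, seeds[4]
        )
        kr_counts.to_csv(out / "counts_kangaroo_rats.csv", index=False)
        gr_counts.to_csv(out / "counts_small_granivores.csv", index=False)
        captures.to_csv(out / "captures.csv", index=False)
        histories_to_frame(histories).to_csv(out / "histories.csv", index=False)
        write_inp(histories, out / "histories.inp")
        plants.to_csv(out / "plants.csv", index=False)
        ground_truth_sidecar(layout, kr_traj, indiv, plant_par,
                             config.seed, out / "ground_truth.yml")
        bundle["stages"].append(stage)

        stage = "flux"
        flux = community_flux(captures)
        # plot-months with no captures carry zero flux
        full = pd.MultiIndex.from_product(
            [layout.plots, list(layout.census_months)], names=["plot", "month"]
        )
        flux = (flux.set_index(["plot", "month"]).reindex(full, fill_value=0.0)
                .reset_index())
        flux["treatment"] = flux["plot"].map(layout.treatment_of_plot)
        flux.to_csv(out / "metabolic_flux.csv", index=False)
        bundle["stages"].append(stage)

        stage = "gams"
        metric_data = {
            "kangaroo_rats": counts_to_gam_frame(kr_counts),
            "small_granivores": counts_to_gam_frame(gr_counts),
            "metabolic_flux": counts_to_gam_frame(flux, "E_total"),
        }
        bundle["gams"] = {}
        for name, mspec in config.metrics.items():
            bundle["gams"][name] = _fit_metric(
                name, metric_data[name], mspec, config, out
            )
            logger.info("fitted %s (%s)", name, mspec.family)
        bundle["stages"].append(stage)

        stage = "influx"
        table, means = tabulate_new_individuals(captures, config.change_month)
        table.to_csv(out / "influx_table.csv", index=False)
        means.to_csv(out / "influx_treatment_means.csv", index=False)
        bundle["influx_means"] = means.to_dict(orient="records")
        bundle["stages"].append(stage)

        stage = "multistrata"
        candidates = [
            ModelCandidate(S_varies=sv, p_varies=False, Psi_varies=pv)
            for sv in (False, True) for pv in (False, True)
        ]
        fitted = [
            fit_multistrata(histories, c, seed=seeds[5]) for c in candidates
        ]
        best = select_model(fitted)
        aic_rows = [
            {"model": c.label(), "n_params": c.n_params,
             "loglik": c.loglik, "AIC": c.AIC} for c in fitted
        ]
        pd.DataFrame(aic_rows).to_csv(out / "multistrata_aic.csv", index=False)
        est_rows = []
        for s in best.params.strata:
            est_rows.append({"parameter": "S", "stratum": s,
                             "estimate": best.params.S[s]})
            est_rows.append({"parameter": "p", "stratum": s,
                             "estimate": best.params.p[s]})
        for a in best.params.strata:
            for b in best.params.strata:
                est_rows.append({"parameter": "Psi", "stratum": f"{a}->{b}",
                                 "estimate": float(best.params.Psi.loc[a, b])})
        pd.DataFrame(est_rows).to_csv(out / "multistrata_estimates.csv", index=False)
        bundle["multistrata"] = {"best": best.label(), "AIC": aic_rows}
        bundle["stages"].append(stage)

        stage = "pcca"
        pcca_rows = []
        for si, season in enumerate(config.plant_seasons):
            sub = plants[plants["season"] == season].reset_index(drop=True)
            species_cols = [c for c in sub.columns
                            if c not in ("sample", "plot", "year", "season", "treatment")]
            tab = AbundanceTable(
                sub[["plot", "year", "season", "treatment"]],
                sqrt_transform(sub[species_cols]),
            )
            res = permutation_test(
                tab, "treatment", "year", n_perm=config.n_perm,
                seed=(seeds[4] + 101 * si) % (2**31),
            )
            pcca_rows.append({
                "season": season, "R2": res.R2, "pseudo_F": res.pseudo_F,
                "perm_p": res.perm_p, "n_perm": res.n_perm,
            })
        pd.DataFrame(pcca_rows).to_csv(out / "pcca_results.csv", index=False)
        bundle["pcca"] = pcca_rows
        bundle["stages"].append(stage)
    except Exception:
        logger.exception("pipeline stage %r failed; earlier outputs persisted", stage)
        raise

    stage = "manifest"
    cfg_doc = _plainify(asdict(config))
    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_doc, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.yml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    config.to_yaml(out / "config.yml")
    bundle["manifest"] = manifest
    return bundle
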