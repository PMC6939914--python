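import numpy as np
import pandas as pd
import pytest

from recolonize.ordination import AbundanceTable, pcca, sqrt_transform
from recolonize.simulate import (
    IndividualSimParams,
    PlantSimParams,
    TrajectoryParams,
    default_layout,
    latent_log_mean,
    simulate_captures,
    simulate_counts,
    simulate_histories,
    simulate_plants,
    spawn_seeds,
)


def test_layout_invariants_enforced():
    with pytest.raises(ValueError, match="inside"):
        default_layout(n_months=20, change_month=25)
    with pytest.raises(ValueError, match="at least 2 plots"):
        default_layout(n_kr_plus=1)


def test_counts_are_deterministic_and_complete(layout, kr_trajectory):
    a = simulate_counts(layout, kr_trajectory, seed=5)
    b = simulate_counts(layout, kr_trajectory, seed=5)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    assert len(a) == len(layout.plots) * len(layout.census_months)
    assert (a["count"] >= 0).all()


def test_degenerate_parameters_collapse_treatments(layout):
    # removal level equal to the control level, no delay, no overshoot,
    # no plot deviations: all treatments share one latent mean
    params = TrajectoryParams(
        control_level=4.0,
        removal_level={"kr_plus": 4.0, "rodent_plus": 4.0},
        recovery_delay={"kr_plus": 0.0, "rodent_plus": 0.0},
        recovery_rate=50.0,
        overshoot_amplitude=0.0,
        plot_sd=0.0,
    )
    counts = simulate_counts(layout, params, seed=0)
    n = len(counts)
    se = np.sqrt(4.0 / n)
    assert abs(counts["count"].mean() - 4.0) < 3 * se
    by_tr = counts.groupby("treatment")["count"].mean()
    assert by_tr.max() - by_tr.min() < 6 * np.sqrt(4.0 / (n / 3))


def test_latent_mean_still_at_removal_level_before_delayed_rise(layout):
    # logistic-trajectory oracle evaluated directly: 11 months before the
    # delayed rise the recovery term is sigmoid(-rate*11) ~ 0
    params = TrajectoryParams(recovery_delay={"kr_plus": 12.0, "rodent_plus": 0.0})
    t = np.array([layout.change_month + 1.0])
    got = latent_log_mean(t, "kr_plus", layout, params)[0]
    rate, delay = params.recovery_rate, 12.0
    depth = np.log(params.removal_level["kr_plus"] / params.control_level)
    expected = np.log(params.control_level) + depth * (
        1.0 - 1.0 / (1.0 + np.exp(-rate * (1.0 - delay)))
    )
    assert got == pytest.approx(expected, abs=1e-12)
    # numerically that is the removal level, not the control level
    assert got == pytest.approx(np.log(0.2), abs=5e-3)
    assert abs(got - np.log(params.control_level)) > 1.0


def test_nonpositive_control_level_rejected():
    with pytest.raises(ValueError, match="positive"):
        TrajectoryParams(control_level=0.0)


# ---------------------------------------------------------------------------
# Histories


def test_perfect_detection_gives_constant_fully_observed_histories(small_layout):
    eps = 1e-9
    params = IndividualSimParams(
        S_by_stratum={"A": 1 - eps, "B": 1 - eps},
        p_by_stratum={"A": 1 - eps, "B": 1 - eps},
        Psi=pd.DataFrame(np.eye(2), index=["A", "B"], columns=["A", "B"]),
    )
    hs = simulate_histories(small_layout, params, 100, seed=1, n_occasions=8)
    for h in hs:
        tail = h.occasions[h.first :]
        assert all(o == tail[0] for o in tail)


def test_zero_survival_means_single_detection(small_layout):
    eps = 1e-9
    params = IndividualSimParams(
        S_by_stratum={"A": eps, "B": eps},
        p_by_stratum={"A": 0.9, "B": 0.9},
        Psi=pd.DataFrame(np.eye(2), index=["A", "B"], columns=["A", "B"]),
    )
    hs = simulate_histories(small_layout, params, 300, seed=2, n_occasions=8)
    assert all(sum(o is not None for o in h.occasions) == 1 for h in hs)


def test_histories_are_legal(small_layout, two_strata_params):
    hs = simulate_histories(small_layout, two_strata_params, 500, seed=3,
                            n_occasions=10)
    for h in hs:
        assert h.occasions[h.first] is not None
        assert all(o is None for o in h.occasions[: h.first])
        assert h.strata <= {"A", "B"}


def test_observed_return_rate_matches_enumeration(small_layout):
    # with shared p, P(detected next occasion | alive in any stratum) = S*p
    S, p = 0.8, 0.5
    params = IndividualSimParams(
        S_by_stratum={"A": S, "B": S},
        p_by_stratum={"A": p, "B": p},
        Psi=pd.DataFrame([[0.7, 0.3], [0.3, 0.7]], index=["A", "B"],
                         columns=["A", "B"]),
    )
    hs = simulate_histories(small_layout, params, 5000, seed=4, n_occasions=3)
    # count detections on the occasion immediately after first capture
    hits = total = 0
    for h in hs:
        if h.first < 2:
            total += 1
            hits += h.occasions[h.first + 1] is not None
    expected = S * p
    se = np.sqrt(expected * (1 - expected) / total)
    assert abs(hits / total - expected) < 3 * se


def test_captures_table_schema_and_mass_positivity(layout, kr_trajectory):
    caps = simulate_captures(layout, kr_trajectory, IndividualSimParams(), seed=0)
    assert set(caps.columns) == {
        "month", "plot", "treatment", "species", "tag", "mass_g"
    }
    assert (caps["mass_g"] > 0).all()
    # tags never appear on two plots in the same month
    assert caps.groupby(["month", "tag"])["plot"].nunique().max() == 1


# ---------------------------------------------------------------------------
# Plants


def test_plants_need_two_years_and_two_species(layout):
    with pytest.raises(ValueError, match="2 years"):
        simulate_plants(layout, PlantSimParams(), [2014], ["winter"], seed=0)
    with pytest.raises(ValueError, match="2 species"):
        PlantSimParams(n_species=1)


def test_no_treatment_signal_gives_near_zero_r2(layout):
    params = PlantSimParams(treatment_effect_sd=0.0)
    df = simulate_plants(layout, params, [2008, 2012, 2014], ["winter"], seed=0)
    tab = AbundanceTable(
        df[["plot", "year", "season", "treatment"]],
        sqrt_transform(df.iloc[:, 5:]),
    )
    assert pcca(tab).R2 < 0.01


def test_no_year_signal_means_conditioning_removes_little(layout):
    params = PlantSimParams(year_effect_sd=0.0, treatment_effect_sd=1.0)
    df = simulate_plants(layout, params, [2008, 2012, 2014], ["winter"], seed=0)
    tab = AbundanceTable(
        df[["plot", "year", "season", "treatment"]],
        sqrt_transform(df.iloc[:, 5:]),
    )
    res = pcca(tab)
    assert res.conditional_inertia / res.total_inertia < 0.02
    assert res.R2 > 0.1


def test_default_treatment_effect_lies_in_calibrated_band(layout):
    """The default effect size comes from a recorded calibration sweep."""
    import pathlib

    sweep = pd.read_csv(
        pathlib.Path(__file__).parent / "data" / "plant_effect_sweep.csv"
    )
    default_sd = PlantSimParams().treatment_effect_sd
    row = sweep.loc[(sweep["treatment_effect_sd"] - default_sd).abs().idxmin()]
    assert 0.03 <= row["mean_R2"] <= 0.05
    # and a fresh simulation at the default lands near the recorded value
    df = simulate_plants(layout, PlantSimParams(),
                         [2008, 2012, 2013, 2014, 2015], ["winter"], seed=10)
    tab = AbundanceTable(
        df[["plot", "year", "season", "treatment"]],
        sqrt_transform(df.iloc[:, 5:]),
    )
    assert 0.02 <= pcca(tab).R2 <= 0.07


def test_seed_splitting_is_stable_and_bounded():
    a = spawn_seeds(123, 5)
    assert a == spawn_seeds(123, 5)
    assert all(0 <= s < 2**31 for s in a)
    assert a != spawn_seeds(124, 5)
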