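import numpy as np
import pandas as pd
import pytest

from recolonize.differences import (
    DifferenceCurve,
    detect_convergence,
    difference_smooth,
)
from recolonize.gam import FitControl, ModelSpec, fit_gam


def _two_treatment_counts(offset: float, seed: int = 0, n_months: int = 72,
                          n_plots: int = 4, level: float = 1.5) -> pd.DataFrame:
    """Two flat treatments whose log means differ by `offset`."""
    rng = np.random.default_rng(seed)
    rows = []
    for tr, lo in (("A", level), ("B", level - offset)):
        for p in range(n_plots):
            y = rng.poisson(np.exp(lo), n_months)
            for m in range(n_months):
                rows.append((f"{tr}{p}", m, int(y[m]), tr))
    return pd.DataFrame(rows, columns=["plot", "month", "count", "treatment"])


@pytest.fixture(scope="module")
def flat_pair_fit():
    data = _two_treatment_counts(offset=1.0).rename(
        columns={"count": "response", "month": "time"}
    )
    return fit_gam(data, ModelSpec(family="poisson", plot_smooths=False))


def test_self_difference_is_identically_zero(flat_pair_fit):
    grid = np.arange(0.0, 72.0)
    curve = difference_smooth(flat_pair_fit, "A", "A", grid)
    assert np.all(curve.diff == 0.0)
    assert np.all(curve.upper - curve.lower == 0.0)


def test_log_offset_recovered(flat_pair_fit):
    grid = np.arange(0.0, 72.0)
    curve = difference_smooth(flat_pair_fit, "A", "B", grid)
    assert 0.9 <= curve.diff.mean() <= 1.1


def test_identical_treatments_intervals_cover_zero():
    data = _two_treatment_counts(offset=0.0, seed=3).rename(
        columns={"count": "response", "month": "time"}
    )
    fit = fit_gam(data, ModelSpec(family="poisson", plot_smooths=False))
    grid = np.arange(0.0, 72.0)
    curve = difference_smooth(fit, "A", "B", grid)
    assert curve.contains_zero().mean() >= 0.90


def test_simultaneous_band_never_narrower_and_levels_nest(flat_pair_fit):
    grid = np.arange(0.0, 72.0)
    point = difference_smooth(flat_pair_fit, "A", "B", grid, level=0.95)
    simul = difference_smooth(
        flat_pair_fit, "A", "B", grid, level=0.95, simultaneous=True, seed=0
    )
    assert np.all(simul.upper - simul.lower >= point.upper - point.lower - 1e-12)
    wide = difference_smooth(flat_pair_fit, "A", "B", grid, level=0.99)
    assert np.all(wide.lower <= point.lower + 1e-12)
    assert np.all(wide.upper >= point.upper - 1e-12)


def test_difference_invariant_to_common_offset():
    rng = np.random.default_rng(5)
    rows = []
    for tr, lo in (("A", 3.0), ("B", 5.0)):
        for p in range(3):
            for m in range(40):
                rows.append((f"{tr}{p}", float(m),
                             lo + 0.05 * m + rng.normal(0, 0.3), tr))
    df = pd.DataFrame(rows, columns=["plot", "time", "response", "treatment"])
    ctrl = FitControl(select="fixed", fixed_lambda=1.0)
    model = ModelSpec(family="gaussian", k_treatment=6, plot_smooths=False)
    grid = np.arange(0.0, 40.0)
    base = difference_smooth(fit_gam(df, model, ctrl), "A", "B", grid)
    shifted = df.assign(response=df["response"] + 7.0)
    moved = difference_smooth(fit_gam(shifted, model, ctrl), "A", "B", grid)
    assert np.abs(base.diff - moved.diff).max() < 1e-8


def _curve_from_inclusion(inside: np.ndarray) -> DifferenceCurve:
    """Construct a difference curve whose band contains zero exactly where
    `inside` is True."""
    n = len(inside)
    diff = np.where(inside, 0.0, 2.0)
    return DifferenceCurve(
        grid=np.arange(n, dtype=float),
        diff=diff,
        lower=diff - 1.0,
        upper=diff + 1.0,
    )


def test_convergence_month_forced_by_constructed_bounds():
    # zero excluded for 21 months after the intervention, contained after
    inside = np.array([False] * 21 + [True] * 19)
    curve = _curve_from_inclusion(inside)
    rep = detect_convergence(curve, intervention=0.0)
    assert rep.months_since_change == 21.0
    assert rep.excursions == []


def test_convergence_immediate_when_zero_always_inside():
    curve = _curve_from_inclusion(np.ones(30, dtype=bool))
    rep = detect_convergence(curve, intervention=4.0)
    assert rep.converge_month == 4.0
    assert rep.months_since_change == 0.0


def test_sustain_rule_skips_short_inclusion_and_reports_excursions():
    # inside at months 3-5 only, excluded until 24, inside onward
    inside = np.zeros(40, dtype=bool)
    inside[3:6] = True
    inside[24:] = True
    curve = _curve_from_inclusion(inside)
    rep = detect_convergence(curve, intervention=0.0, sustain=6.0)
    assert rep.months_since_change == 24.0
    # with a finite sustain, a later excursion is reported, not clock-resetting
    inside2 = np.zeros(40, dtype=bool)
    inside2[10:] = True
    inside2[30:32] = False
    rep2 = detect_convergence(_curve_from_inclusion(inside2), 0.0, sustain=6.0)
    assert rep2.months_since_change == 10.0
    assert rep2.excursions == [(30.0, 31.0)]


def test_never_converging_curve_reports_none():
    curve = _curve_from_inclusion(np.zeros(20, dtype=bool))
    rep = detect_convergence(curve, intervention=0.0)
    assert rep.converge_month is None and rep.months_since_change is None


def test_intervention_outside_grid_rejected():
    curve = _curve_from_inclusion(np.ones(10, dtype=bool))
    with pytest.raises(ValueError, match="outside"):
        detect_convergence(curve, intervention=99.0)
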