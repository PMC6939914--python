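"""Difference-of-smooths credible intervals and convergence timing.

The link-scale difference between the control smooth and each treatment
smooth, with 95% credible bounds from the GAM's Bayesian posterior, tells
us when a treatment became statistically indistinguishable from controls:
the first month from which the interval keeps containing zero (sustained
for 6 months here).
"""

import numpy as np

from recolonize import (
    ModelSpec,
    TrajectoryParams,
    default_layout,
    detect_convergence,
    difference_smooth,
    fit_gam,
    simulate_counts,
)

layout = default_layout()
counts = simulate_counts(layout, TrajectoryParams(), seed=0)
fit = fit_gam(
    counts.rename(columns={"count": "response", "month": "time"}),
    ModelSpec(family="poisson"),
)

grid = np.arange(26.0, 72.0)  # from the treatment change onward
for treatment in ("rodent_plus", "kr_plus"):
    curve = difference_smooth(fit, "control", treatment, grid, level=0.95)
    report = detect_convergence(curve, intervention=26.0, sustain=6.0)
    print(f"{treatment}: converged {report.months_since_change:.0f} months "
          f"after the change (month {report.converge_month:.0f})")
    if report.excursions:
        print(f"  later excursions outside zero: {report.excursions}")

print("\nPlots that already held a rodent community (kr_plus) take about "
      "two years to reach control levels; empty plots (rodent_plus) "
      "converge within a few months — the generator's ground truth.")
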