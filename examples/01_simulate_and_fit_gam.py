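"""Simulate kangaroo-rat counts and fit treatment-specific smooths.

Generates monthly counts for 10 plots (4 control, 3 kangaroo-rat+,
3 rodent+) with the treatment change at month 26, fits a Poisson GAM with
a smooth of time per treatment plus plot-deviation smooths, and prints the
effective degrees of freedom of each treatment smooth.  A flat control
smooth (edf near 0) and wiggly recovery smooths are the expected picture.
"""

import numpy as np

from recolonize import (
    ModelSpec,
    TrajectoryParams,
    default_layout,
    fit_gam,
    predict_treatment_curve,
    simulate_counts,
)

layout = default_layout()
params = TrajectoryParams()  # kr+ delayed 21 months, rodent+ immediate
counts = simulate_counts(layout, params, seed=0)
print(counts.head())

data = counts.rename(columns={"count": "response", "month": "time"})
fit = fit_gam(data, ModelSpec(family="poisson"))

print("\nEffective degrees of freedom per treatment smooth:")
for name, edf in fit.edf.items():
    if "plot" not in name:
        print(f"  {name:24s} {edf:6.2f}")

grid = np.array([0.0, 26.0, 40.0, 71.0])
for tr in fit.treatment_levels:
    est, se = predict_treatment_curve(fit, tr, grid)
    mean_counts = np.exp(est)
    print(f"\n{tr}: mean counts at months {grid.astype(int).tolist()} "
          f"= {np.round(mean_counts, 2).tolist()}")
print("\nControls stay near their long-term level; the treated plots start "
      "near zero and recover after the month-26 change.")
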