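"""Community metabolic flux from body masses, and its Tweedie GAM.

Individual metabolic rate scales as mass^(3/4); summing over the
seed-eating individuals caught on a plot in a census gives the community's
energy use, a smoother community-level signal than any single species'
counts.  Flux is non-negative with exact zeros (empty plot-months), hence
the Tweedie family.
"""

import pandas as pd

from recolonize import (
    IndividualSimParams,
    ModelSpec,
    TrajectoryParams,
    community_flux,
    default_layout,
    fit_gam,
    metabolic_rate,
    simulate_captures,
)

print(f"metabolic_rate(16 g)  = {metabolic_rate(16.0):.1f}  (16^0.75 = 8)")
print(f"metabolic_rate(81 g)  = {metabolic_rate(81.0):.1f}  (81^0.75 = 27)")
print(f"metabolic_rate(45 g)  = {metabolic_rate(45.0):.2f}  (a kangaroo rat)")

layout = default_layout()
caps = simulate_captures(layout, TrajectoryParams(), IndividualSimParams(),
                         seed=0)
flux = community_flux(caps)
flux["treatment"] = flux["plot"].map(layout.treatment_of_plot)
print("\nmean flux per plot-month by treatment and period:")
print(flux.assign(post=flux.month >= 26)
      .groupby(["treatment", "post"])["E_total"].mean().round(1))

fit = fit_gam(
    flux.rename(columns={"E_total": "response", "month": "time"}),
    ModelSpec(family="tweedie", tweedie_power=1.5),
)
print(f"\nTweedie GAM scale estimate phi = {fit.phi:.2f}; treatment smooth "
      f"edf: " + ", ".join(
          f"{k.split(':')[1]}={v:.1f}" for k, v in fit.edf.items()
          if "plot" not in k))
print("Flux on the removal plots climbs toward control levels after the "
      "change, tracking the recolonization.")
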