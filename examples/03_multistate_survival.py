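"""Multistate capture-recapture: survival and movement between treatments.

Simulates tagged-individual histories whose stratum is the treatment type
of the plot, fits the candidate model set (survival and transitions with
or without a strata effect), selects by AIC and prints the estimates.
"""

from recolonize import (
    IndividualSimParams,
    ModelCandidate,
    default_layout,
    fit_multistrata,
    select_model,
    simulate_histories,
)

layout = default_layout()
truth = IndividualSimParams()  # S: control .85, kr+ .90, rodent+ .80
histories = simulate_histories(layout, truth, n_individuals=2000, seed=1)
print(f"{len(histories)} histories over "
      f"{len(histories[0].occasions)} monthly occasions")

candidates = [
    ModelCandidate(S_varies=sv, p_varies=False, Psi_varies=pv)
    for sv in (False, True) for pv in (False, True)
]
fitted = [fit_multistrata(histories, c, seed=0) for c in candidates]
print("\nAIC table:")
for c in sorted(fitted, key=lambda c: c.AIC):
    print(f"  {c.label():34s} k={c.n_params:2d}  AIC={c.AIC:9.1f}")

best = select_model(fitted)
print(f"\nbest: {best.label()}")
print("apparent survival by treatment:")
for s, v in best.params.S.items():
    print(f"  {s:12s} {v:.3f}   (truth {truth.S_by_stratum[s]:.2f})")
print("transition matrix (rows: from, cols: to):")
print(best.params.Psi.round(3))
print("\nMonthly apparent survival and the strong stay-put diagonal are "
      "recovered from detection/non-detection sequences alone.")
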