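"""Partial CCA of plant composition: treatment effect after removing year.

Plant quadrat counts are square-root transformed, year-to-year turnover is
conditioned out, and the share of chi-square inertia attributable to
treatment is tested by free permutation of samples.
"""

from recolonize import (
    AbundanceTable,
    PlantSimParams,
    default_layout,
    permutation_test,
    simulate_plants,
    sqrt_transform,
)

layout = default_layout()
plants = simulate_plants(
    layout, PlantSimParams(),
    years=[2008, 2012, 2013, 2014, 2015], seasons=["winter"], seed=0,
)
species = [c for c in plants.columns
           if c not in ("sample", "plot", "year", "season", "treatment")]
table = AbundanceTable(
    plants[["plot", "year", "season", "treatment"]],
    sqrt_transform(plants[species]),
)

res = permutation_test(table, "treatment", "year", n_perm=999, seed=0)
print(f"total inertia        {res.total_inertia:.4f}")
print(f"year (conditioned)   {res.conditional_inertia:.4f}")
print(f"treatment (tested)   {res.constrained_inertia:.4f}")
print(f"R^2 = {res.R2:.3f}   pseudo-F = {res.pseudo_F:.2f}   "
      f"p = {res.perm_p:.4f} ({res.n_perm} permutations)")
print("\nThe treatment effect is real but small — a few percent of "
      "community variation — while year dominates, mirroring a community "
      "whose composition turns over strongly between years.")
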