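# recolonize

Analysis toolkit for plot-level recolonization experiments on desert rodent
communities — the kind of long-term manipulation where fenced plots exclude a
dominant competitor (kangaroo rats, *Dipodomys*) or the whole rodent
community, and the gates are later opened so recolonization dynamics can be
compared against long-term controls.

The package implements the full inference stack such an experiment needs, and
a seeded synthetic-data generator that emulates the design (10 plots in three
treatment groups, monthly censuses over six years, a treatment change partway
through) so that every stage can be validated against known ground truth.

## What it computes

**Treatment trajectories and convergence times.** Counts (or flux) per plot
per month are modelled with a penalized-spline GAM on the log link:

    log E[y_it] = a_{tr(i)} + f_{tr(i)}(t) + g_i(t)

with a separate smooth of time `f` per treatment group, plot-specific
deviation smooths `g_i` (shrunk toward zero, sharing one smoothing
parameter), a Poisson family for counts and a Tweedie family
(`Var ∝ μ^p`, `1 < p < 2`) for metabolic flux. Smoothing parameters are
selected by GCV. The treatment effect is read off as the link-scale
difference of two treatment smooths, `d(t) = c(t)'β`, with a 95% credible
interval from the Bayesian posterior `β ~ N(β̂, (X'WX + Σλ_j S_j)⁻¹ φ)`;
the *convergence month* is the first post-intervention month from which the
interval contains zero for a sustained run of months.

**Multistate capture–recapture.** Tagged-individual histories whose stratum
is the treatment type are fitted with the Arnason–Schwarz conditional
likelihood (survive `S` → move `Psi` → detect `p`, latent strata
marginalized by a forward recursion with an absorbing dead state). Candidate
models with or without strata effects on `S` and `Psi` are ranked by AIC.

**Metabolic flux.** Individual metabolic rate is `E = m^(3/4)` (mass in
grams, arbitrary units); community flux is the per-plot per-census sum over
the seed-eating species, each tagged individual counted once per month.

**Plant composition.** Partial canonical correspondence analysis: square
root transformed quadrat abundances on the chi-square (correspondence
analysis) scale, year conditioned out by weighted projection, the treatment
share of inertia (`R²`) tested by permutation of samples with the condition
re-projected each time.

## Worked example

```sh
python examples/02_difference_curves_and_convergence.py
```

```
rodent_plus: converged 6 months after the change (month 32)
kr_plus: converged 26 months after the change (month 52)
```

The generator's ground truth delays recovery by 21 months on plots that
already held a rodent community (`kr_plus`) and not at all on emptied plots
(`rodent_plus`); the fitted difference curves recover that contrast — fast
convergence (months) where no residents were present, roughly two years
where an established community had to be displaced. The other examples show
the survival/transition estimates (`03`, recovering S within ~0.005 at
n=2000 individuals), the plant ordination (`04`, treatment `R² ≈ 0.037`,
permutation `p = 0.001`) and the flux pipeline (`05`).

A thin CLI wraps the same calls (`recolonize simulate | fit-gam | diff |
converge | influx | markfit | pcca | flux | run-all`); `run-all` executes
the whole pipeline from a YAML config and writes every table as CSV plus a
run manifest.

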