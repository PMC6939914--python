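# Methods

This note records the statistical machinery, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## The GAM engine

Smooths are cubic B-splines on quantile-spaced knots with a
derivative-based wiggliness penalty: `∫ f''(t)² dt` for `penalty_order=2`
(default), `∫ f'(t)²` for order 1. The derivative penalty (rather than a
coefficient-difference penalty) makes straight lines exactly free under
order 2 on uneven knots. Each smooth carries a sum-to-zero constraint
absorbed by an orthonormal reparameterization, so `k` basis functions yield
`k − 1` columns next to an explicit intercept per treatment.

Null-space shrinkage: every smooth's penalty is augmented with a small
multiple (0.01 of the mean non-null eigenvalue) of the projection onto its
penalty null space. This lets a single smoothing parameter take a smooth all
the way to zero — a no-signal treatment smooth reaches edf ≈ 0 instead of
edf ≈ 1, and plot smooths behave as random smooth deviations. The weight is
kept small so that moderate smoothing does not bias the level/trend
component; at 0.1 the bias was measurable on sinusoidal test signals.

**Identifiability of plot deviations.** Plot smooths (k=8, one shared
smoothing parameter, null space shrunk) could otherwise represent a
treatment-level signal: the three plots of a treatment moving together are
indistinguishable, in penalized-likelihood terms, from the treatment smooth
itself, and GCV has no preference between the two representations. Each
plot's deviation columns are therefore residualized against
`[1, treatment-smooth basis]` on that plot's rows, making treatment-level
signal identifiable to the treatment smooth alone. The difference curves
exclude plot columns, so this is what makes them mean what they claim.

**Families.** Poisson (scale fixed at 1) for counts; Tweedie with
`Var = φ μ^p` for flux, power fixed at `p = 1.5` by default (the data are
non-negative with exact zeros; the fitted φ is a Pearson estimate and the
tests check it tracks a compound Poisson–gamma generator within 25%);
Gaussian/identity for validation against least squares. `fit_gam` with
`select="fixed", fixed_lambda=0` reproduces OLS on the same design to 1e-8.

**Smoothing selection.** GCV
`n·||√W(z − Xβ)||² / (n − γ·tr(A))²` with γ = 1.4 (the standard inflation
against GCV undersmoothing), minimized coordinate-wise by bounded Brent
search on log₁₀λ ∈ [−6, 9] inside a performance-iteration outer loop
(penalized IRLS to convergence, then re-selection on the working model, at
most 10 rounds). Initialization is deliberately asymmetric — treatment
smooths start flexible (λ = 0.01), plot smooths start stiff (λ = 10⁶) — and
the best state across outer rounds (by its own GCV) is kept, both guards
against the coordinate search wandering between local optima. Exact REML as
in mgcv is not implemented; this is the main source of numerical divergence
from mgcv fits, though on shared fixtures (constant and sinusoidal Poisson
data) mgcv's GCV and this one pick near-identical effective degrees of
freedom, including the same occasional spurious-wiggle realizations.

Convergence: relative deviance change below 1e-8, at most 200 IRLS
iterations; non-convergence raises an error carrying the deviance trace.
An all-zero response is fitted but flagged degenerate.

Defaults `k = 20` per treatment smooth (72 monthly censuses) and `k = 8`
per plot smooth are generous relative to the dynamics being tracked and are
not sensitive choices; the basis dimension only caps, never forces,
complexity.

## Difference curves and convergence

The difference between two treatments on the link scale is the linear
functional `c'β` with `c` the difference of prediction rows (intercepts
included, plot columns zero). Pointwise bounds use the normal quantile with
the posterior SE `√(c'Vc)`; simultaneous bounds (optional) use the max-|t|
criterion over 10 000 posterior draws and are never narrower than the
pointwise ones. The default interval is pointwise 95%, matching how such
intervals are usually reported; self-differences are exactly zero with
zero-width intervals.

`detect_convergence` returns the earliest post-intervention grid time from
which the interval contains zero for `sustain` consecutive months. The
library default (`sustain=None`) demands inclusion through the end of the
series; the *pipeline* default is `sustain=6` months, with later
zero-exclusions reported as excursions rather than resetting the clock.
Rationale: recolonization trajectories oscillate, and a 2–4-month noise
excursion late in the series would otherwise push the detected convergence
far past the point where the treatments became indistinguishable — on
synthetic data with known truth, the end-of-series rule misses the true
delay by a year on some realizations while the 6-month rule recovers the
delay contrast within ±4 months across seeds.

## Multistate capture–recapture

Arnason–Schwarz conditional likelihood with the standard event order:
survive with the current stratum's `S`, then move by the `Psi` row, then be
detected with the destination stratum's `p`. The forward recursion carries
per-stratum alive probabilities plus an absorbing dead/emigrated state
(compatible only with all-non-detection tails) and is vectorized across
histories. Apparent survival confounds death with permanent emigration, as
always without dead recoveries.

Parameters live on logit (S, p) and multinomial-logit (Psi rows, diagonal
as reference) scales, maximized by L-BFGS from a neutral start plus three
seeded random restarts. The candidate set varies S and Psi by stratum;
`p` is shared across strata by default. The constrained Psi is a single
move probability split equally among destination strata — the simplest
"no strata effect on movement" reading. AIC = 2k − 2ℓ, ties to the smaller
model. Estimates of p at the boundary are flagged.

Tests pin the likelihood to brute-force latent-path enumeration (T ≤ 5),
total-probability closure, relabelling invariance, an independently coded
Cormack–Jolly–Seber oracle in the single-stratum case, and parameter
recovery within 0.05 at n = 3000.

## Metabolic flux

`E = m^0.75` with proportionality constant 1: flux is only ever used
comparatively, so units are arbitrary. Community flux sums over the
seed-eating community (3 kangaroo-rat species plus 10 small granivores,
editable species sets) per plot per census; within-month recaptures of a
tag count once; missing masses are imputed by the within-dataset species
mean and individuals with no conspecific mass anywhere are dropped with a
warning.

## Partial CCA

The community matrix (after a single square-root transform) is standardized
as in correspondence analysis: `Q̄ = (P − rc')/√(rc')` with row/column
masses `r`, `c`; total inertia is `ΣQ̄²`. Conditioning and constraint are
weighted projections onto factor indicator designs scaled by `√r` (the
constraint residualized on the condition), giving the decomposition
total = conditional + constrained + residual, closing to 1e-9. `R²` is
constrained/total — the raw, not adjusted, share. The pseudo-F statistic is
`(constrained/q)/(residual/df_res)` with `df_res = n − 1 − q − rank(cond)`;
the permutation test permutes sample rows (freely by default, within years
as an option) and re-projects the condition each time,
`p = (1 + #{F* ≥ F})/(n_perm + 1)`. Seasons are analysed as separate
tables, never pooled. During development the implementation was checked
against vegan's `cca`/`anova` output on shared data and agrees to all
printed digits.

## The synthetic-data generator

The generator emulates: 10 plots (4 control, 3 kangaroo-rat+, 3 rodent+),
72 monthly censuses with the treatment change at month 26; Poisson counts
around log-linear latent trajectories; individual histories obeying
survive–move–detect; lognormal body masses per species; plant quadrat
counts (16 per plot, negative binomial) with a dominant year effect and a
weak treatment effect.

The latent count trajectory is
`log μ = log(control_level) + depth·(1 − logistic(rate·(t − change − delay)))`
with `depth = log(removal_level/control_level)`, plus a damped seasonal
sinusoid (amplitude 0.3 on the log scale, 12-month period, damping
0.08/month) on rodent+ plots only — the simplest form producing fast
oscillatory recovery on emptied plots and slow monotone recovery where a
resident community is present. Defaults: control level 4 kangaroo rats per
plot per month, removal levels 0.1–0.2 (stray transients), recovery delays
21 months (kr+) and 0 (rodent+) — the delay contrast matching the roughly
two-year versus few-month recovery the experiment is known for — rate
0.6/month, plot-deviation SD 0.15 (log scale) realized as smooth mean-zero
random spline functions, not white noise. Small-granivore trajectories use
control 5.7, removal levels 7.8 (kr+, released from competition) and 3.1
(rodent+), converging immediately after the change.

Multistate defaults: monthly apparent survival 0.85/0.90/0.80
(control/kr+/rodent+), shared recapture 0.5, strong stay-put diagonal in
Psi with movement toward kr+ rarest. Masses: kangaroo rats centred 45–130 g
by species, small granivores 8–30 g.

The plant treatment-effect SD (0.3 on the log scale) was calibrated by a
simulation sweep (recorded in `tests/data/plant_effect_sweep.csv`) so the
downstream pCCA attributes ~3–5% of inertia to treatment at the default
design — the regime of a weak but permutation-detectable effect.

All randomness flows from integer seeds; the pipeline derives per-stage
child seeds from one master seed via `numpy.random.SeedSequence`.

**What the generator does not emulate**, hence what green tests do not
show about field data: species-level dynamics within the pooled counts, a
realistic species mix or age structure, weather and seasonality in counts
(beyond the rodent+ overshoot), trap saturation, tag loss, and the
demographic coupling between influx and abundance — the generator's influx
contrast between treatments is muted relative to the strong influx pulse a
real colonization wave produces, so influx tabulation is tested for
correctness of counting, not for effect size. Census months are idealized
as exact calendar months; real trapping nights straddling month boundaries
are an ingest-mapping concern (`month` must be a census-period index).

## Numerical choices and degenerate inputs

A tiny ridge (1e-10 relative) stabilizes the penalized Cholesky when
λ → 0 on rank-deficient working designs. Linear predictors are clipped at
±30 before exponentiation. Probabilities entering the multistate likelihood
are floored at 1e-300 before the log. The pCCA raises on tables with zero
inertia (identical rows), on constraints aliased with the condition, and on
within-year permutation with singleton years. `detect_convergence` with an
interval that never contains zero reports "no convergence" rather than
erroring. Ties in AIC go to the smaller model by explicit rule.

## Scale of the shipped validation

The test suite and acceptance script run entirely on synthetic data at
deliberately modest sizes — 720 plot-months per GAM metric, 1500–3000
capture histories, 160–800 plant samples, 199–999 permutations, 50-replicate
calibration studies — sizes at which every stage's statistical behaviour is
measurable while the whole suite stays fast. Field-scale datasets of the
archived experiment are one to two orders of magnitude larger in individuals
but identical in structure; `ingest_captures`/`ingest_plants` accept any CSV
with the documented columns.
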