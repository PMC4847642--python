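# Methods

## Model

Two individual-level survival datasets are modelled jointly, with time 0 at
study entry (around age 60 in the intended applications) and all times in
years.

**Population data** (long follow-up, causes of death recorded). Each cause
k ∈ {1, 2} has an independent parametric time-to-death distribution; the
default family is Weibull with shape α_k and rate λ_k, so h_k(t) =
λ_k α_k t^{α_k−1} and Λ_k(t) = λ_k t^{α_k}. The Gompertz alternative uses
h_k(t) = λ_k e^{α_k t}, Λ_k(t) = (λ_k/α_k)(e^{α_k t} − 1), with the
removable singularity at α_k → 0 evaluated in the exponential limit
Λ = λ_k t. Under independent competing risks each individual contributes,
for every cause, an event term if they died of that cause and a survivor
term at their observed time otherwise — i.e. a death from cause 2 is
censoring for cause 1 at the same time.

**Study data** (short follow-up, causes unrecorded). The death time is the
minimum of latent cause-specific times, so overall mortality follows a
polyhazard distribution with hazard Σ_k e^{w_k} h_k(t), where w_k is the
group's log hazard ratio on component k. The core assumption is a
proportional effect on the cause of interest only: w₁ = β, w₂ = 0. A second
treatment arm multiplies component 1 by e^{γ+β}. The code permits arbitrary
per-component effects (needed, e.g., to explore a third cause grouped with
the cause of interest).

**Joint likelihood.** The log-likelihood is the sum of the study polyhazard
term, the per-cause population terms, and (if individual data exist) a
second-arm polyhazard term, with component parameters shared throughout.
All accumulation is in log space; the study event term uses a two-term
log-sum-exp.

**Outputs.** For each posterior draw, lifetime mean survival per arm is the
area under that draw's survivor curve; life years gained is the difference
between two arms' means. Posterior summaries are means, sds and equal-tailed
95% quantile intervals (the equal-tailed choice is ours; highest-density
intervals would differ slightly for skewed quantities). Posterior mean
deviance D̄ = E[−2 log L] is stored per likelihood component; it is
comparable only between models with identical structure (e.g. poly-Weibull
vs poly-Gompertz), not across different data decompositions.

## Comparator models

- **All-cause Weibull PH**: one Weibull for overall mortality, study rate
  e^β λ, treated-arm rate e^{β+γ} λ, common shape. Correct only when the
  component shapes coincide.
- **Piecewise-exponential PH ("Cox-like")**: a shared baseline hazard,
  piecewise constant with change points at every observed death time
  (duplicates merged), study group scaled by e^β. A death at a change point
  uses the hazard of the interval it terminates. The final interval is
  open-ended: its hazard extrapolates beyond the last observed death, which
  is a modelling decision — the area under the extrapolated survivor then
  has an exact closed form per draw. Because the population records run to
  death, the change points cover the whole age range and the extrapolated
  tail carries little mass.

## Priors

Defaults express weak beliefs on interpretable scales:

- Weibull scale σ_k = λ_k^{−1/α_k} ~ Uniform(0, 100) years. A single
  component's mean lifetime is σ Γ(1 + 1/α), so this caps prior mean
  survival at roughly 60–100 years past entry; the prior-predictive median
  is ≈ 44 years.
- log α_k ~ Normal(0.5, 0.78²), the sd chosen so the hazard ratio over a
  doubling of time since entry, 2^{α−1}, has 95% interval ≈ (0.64, 100)
  with prior mean 1.5 (hazards expected to rise with age).
- β ~ Normal(0, 2.5²): hazard-ratio interval ≈ (1/150, 150).
- γ ~ Normal(−log HR, sd), built from a published treatment hazard ratio;
  the sd defaults to (log hi − log lo)/(2·1.96) from the 95% CI and can be
  set directly when reproducing a published prior sd that the symmetric
  formula does not exactly recover.
- Identifiability ordering λ₁ < λ₂, implemented on the scale axis as
  σ₁ > σ₂ (equivalently, the cause of interest is the one with the longer
  cause-specific survival scale). It is enforced as prior-support
  truncation inside the log-posterior, which is exact for the ensemble
  sampler. All six built-in scenarios' generating parameters satisfy it.
- Piecewise baseline: independent Gamma(c·μ_j, c) per interval with
  c = 200 (high prior variance around the mean). In the simulation harness
  μ_j is the generating population hazard at interval midpoints; on real
  data the default is a smoothed Nelson–Aalen increment estimate
  (rolling-mean window 11), overridable by array or callable.
- Gompertz slopes α_k ~ Normal, calibrated so e^{10 α} — the hazard ratio
  over the doubling 10 → 20 years — has the same 95% interval as the
  Weibull doubling-time hazard ratio above. This calibration (and the
  reference doubling) is an interpretation, flagged as such.

The Uniform prior is placed on the Weibull *scale* σ rather than on the
reciprocal rate 1/λ: only the scale reading yields the mean-survival bound
that motivates the prior, and rates as small as 10⁻⁷ (as in the built-in
scenarios) are otherwise excluded from the support.

## Computation

- **Samplers.** The parametric variants use the affine-invariant ensemble
  sampler (emcee) with a vectorised log-posterior; defaults are 32 walkers,
  1700 iterations, 700 burn-in, thinning 8 (≈ 4000 retained draws), sized
  so the joint poly-Weibull fit on scenario-sized data usually passes
  split-R̂ < 1.05 (walkers treated as chains; arviz). Fits that miss the
  threshold are flagged with a warning and `converged_ = False`, never
  silently. The piecewise model uses Gibbs sampling — interval hazards have
  conjugate Gamma full conditionals given β; β (and γ with second-arm data)
  use univariate slice sampling; γ without second-arm data is drawn exactly
  from its prior — with 4 chains of 750 iterations (250 burn-in). All
  randomness derives from a single `random_state` via `SeedSequence`, so
  fits are bit-reproducible.
- **Parameterisation.** Sampling coordinates are (log α_k, σ_k, β[, γ]) for
  poly-Weibull, (α_k, 1/λ_k, β[, γ]) for poly-Gompertz and (log α, σ, β[, γ])
  for the all-cause Weibull.
- **Mean-survival integration.** Point evaluations use adaptive quadrature
  (absolute tolerance 1e-6, well inside the documented 1e-4 years) on
  [0, T_max], where T_max is the first time the survivor drops below 1e-10,
  capped at 200 years — lifetimes 200 years past entry have no support in
  human applications (an uncapped mode exists for closed-form checks).
  Per-draw integrals over thousands of posterior draws use fixed
  Gauss–Legendre panels (64 nodes on each of [0,10], [10,40], [40,100],
  [100,200]), which agree with adaptive quadrature to < 1e-6 years on the
  relevant parameter ranges (tested). Single-Weibull means use the closed
  form λ^{−1/α} Γ(1 + 1/α); piecewise means use the exact per-interval
  closed form with the final hazard extrapolated.
- **Degenerate inputs.** Nonpositive shapes/rates, times ≤ 0, events
  outside {0,1}, cause labels on censored rows, unknown group labels and
  zero-variance treatment priors are rejected with explicit errors.

## Simulation harness

Six scenarios cross three shape configurations — (1.7, 1.7), (1.5, 2),
(1.5, 4.5), with population rates (0.0015, 0.0022) for the first two and
(1.5e-3, 1.5e-7) for the third — with β ∈ {1.5, 3}. The study group is
always the population with the cause-1 rate multiplied by e^β, so the
poly-Weibull is the generating model in every scenario; the scenarios
differ in how quickly cause 1's share of mortality declines with age. The
implied true mean survivals are 24.04/17.58/26.96 years (populations),
14.32/14.22/19.78 (study, β = 1.5) and 6.72/8.09/9.20 (study, β = 3).

Per replicate, 1000 population records are drawn as latent cause-specific
Weibull minima and followed to death (they stand in for life-table controls
whose complete lifetimes are known), and 500 study records are censored by
min(Exponential(rate), 10 years) with rate 0.15 (β = 1.5) or 0.4 (β = 3) —
under the ICD-like scenario about 15% of study patients have observed
deaths. Replicate seeds are spawned from the master seed by counter, so any
replicate reruns in isolation; datasets are shared across fitted models.
Reported operating characteristics are the signed mean bias of the
posterior-mean study mean survival (percentage bias relative to the
analytic truth) and the coverage of equal-tailed 95% credible intervals.
Fits that raise are recorded and excluded, with the count reported.

The default problem sizes — 50 replicates for the headline experiment,
10 for the in-suite check — are our choice of scale; the bias contrast
between the all-cause Weibull (≈ −6 years, zero coverage under Model 3,
β = 1.5; the large-sample pseudo-true fit gives −6.6) and the poly-Weibull
(|bias| < 1 year) is stable well below these sizes.

## Life-table population synthesis

Matched controls are sampled per study patient (default 20 per patient,
enough that population sampling noise is negligible next to study-data
uncertainty): walk the period life table from the patient's entry age,
dying in a year with probability q(age, sex); the terminal age forces
q = 1, so every control dies and the dataset is censoring-free. Death
times get a Uniform(0,1)-year within-year offset — the annual walk only
locates the death year, and continuous likelihoods need untied times.
Ages advance with calendar years against a single period table (no cohort
projection). A cause label (cause of interest vs other) is drawn with the
fraction for the age group *at death*. The misclassification sensitivity
transform relabels each cause-1 death as cause 2 independently with a
given probability, leaving times and event indicators untouched.

The bundled `synthetic_life_table()` / `synthetic_cause_fractions()` are
Gompertz–Makeham constructions for tests and examples, not official
statistics.

## What the synthetic data do and do not show

The generator produces exactly the model's assumed world: independent
additive causes, proportional cause-specific effects constant in time,
Weibull margins, non-informative censoring, and (in the harness) fully
observed population lifetimes. Passing tests therefore demonstrate correct
inference and the cost of ignoring cause structure *within* that world;
they say nothing about dependent competing risks, time-varying treatment
effects, cause misclassification beyond the simple random relabelling
transform, covariate heterogeneity, or model families outside
Weibull/Gompertz — all of which real cohort data may exhibit.

## Known limitations

- K = 2 latent causes in the fitted models (the math layer supports any K).
- No left truncation, interval censoring or covariate regression on shapes.
- β is weakly identified when the component hazards are similar over the
  observed window; the population data and the ordering constraint carry
  the identification, and credible intervals for β can remain wide.
- The ensemble sampler treats walkers as chains for R̂; this is the
  standard practice but is a conservative proxy for independent chains.
- D̄ comparisons assume equal model complexity; no DIC/WAIC is computed.
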