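# polyhazard

Bayesian survival extrapolation with cause-specific hazards.

Health-economic evaluations need lifetime mean survival — the area under
the survivor curve, E(T) = ∫₀^∞ S(t) dt — for patients whose follow-up
covers only a few years. A common fix is to borrow long-term general-population
mortality and assume the study cohort's *all-cause* hazard is proportional to
the population's. That assumption fails whenever the cohort's excess risk is
concentrated in one cause of death whose share of overall mortality changes
with age, and the resulting extrapolations can be badly biased.

`polyhazard` implements the cause-specific alternative. Population survival is
modelled with independent parametric hazards per cause of death, h_k(t)
(Weibull λ_k α_k t^{α_k−1} or Gompertz λ_k e^{α_k t}). Study patients — whose
causes of death are unrecorded — follow a **polyhazard** model: their overall
hazard is the sum of the latent cause-specific hazards, with a proportional
effect e^β only on the cause of interest (cause 1),

    h_pop(t)   = h₁(t) + h₂(t)
    h_study(t) = e^β h₁(t) + h₂(t)           S_study(t) = exp(−e^β Λ₁(t) − Λ₂(t))
    h_treat(t) = e^{γ+β} h₁(t) + h₂(t)

where γ is a treatment log hazard ratio, typically supplied as a prior built
from a published meta-analysis hazard ratio. All data sources are modelled
jointly — cause-labelled population records contribute one likelihood term per
cause (competing-risks encoding), unlabelled study records contribute the
polyhazard term — and the posterior is sampled by MCMC. Per-draw integration
of the survivor function yields posterior distributions of lifetime mean
survival per arm and of life years gained (LYG) between treatments.

The package also ships the two standard comparators (an all-cause
proportional-hazards Weibull and a semi-parametric piecewise-constant-hazard
"Cox-like" model), a simulation harness that measures the bias and coverage
of all three under shifting cause composition, and a life-table sampler that
builds matched general-population control datasets from annual death
probabilities and cause-of-death fractions.

## Worked example

Simulate an ICD-like scenario (population with two Weibull causes of death,
shapes 1.5 and 2; a study cohort with e^1.5 times the cause-1 hazard, censored
at 10 years), then fit the joint poly-Weibull model with a treatment-effect
prior from a published hazard ratio of 0.50 (95% CI 0.37–0.67):

```python
from polyhazard import PolyhazardExtrapolator, generate_scenario_data, get_scenario

pop, study = generate_scenario_data(get_scenario("model2_b15"), seed=11)
est = PolyhazardExtrapolator(
    treatment_hazard_ratio=0.5, treatment_ci=(0.37, 0.67),
    n_steps=4000, n_burn=1500, thin=10, random_state=5,
).fit(pop.concat(study))
print(est.posterior_.summary().round(4))
```

```
                             mean      sd     2.5%    97.5%
alpha1                     1.5536  0.1098   1.3472   1.7741
alpha2                     2.0174  0.0521   1.9159   2.1230
lambda1                    0.0014  0.0005   0.0007   0.0026
lambda2                    0.0022  0.0004   0.0015   0.0030
beta                       0.2180  0.9924  -2.7129   1.2682
gamma                      0.7016  0.1528   0.3992   0.9993
mean_survival_population  17.3251  0.2976  16.7467  17.9037
mean_survival_study       16.6683  0.9136  14.8997  18.4463
mean_survival_treated     15.1504  1.5544  12.2365  18.2942
life_years_gained          1.5179  0.7445   0.0867   2.9989
```

The component parameters recover the generating values (shapes 1.5/2.0, rates
0.0015/0.0022). The study cohort's extrapolated life expectancy is 16.7 years
(95% CrI 14.9–18.4). β is weakly identified here — over the 10-year follow-up
the two causes' hazards are of similar size, so many (β, λ₁) combinations fit
the short-term data — which is exactly why the long-term population records
are in the model. The treated arm contributes no individual data, so the
posterior of γ (mean 0.70, sd 0.15) simply reproduces its prior
(−log 0.50 = 0.693, sd 0.152), and switching treatments is worth about 1.5
life years in expectation.

The same workflow is available from the shell:

```sh
polyhazard simulate --scenario model2_b15 --seed 11 --out data/
polyhazard fit --study data/study.csv --population data/population.csv \
    --variant poly-weibull --treatment-hr 0.5 --treatment-ci 0.37 0.67 \
    --seed 5 --out fit/
polyhazard sim-study --scenario model3_b15 --models all --reps 50 --seed 1 --out sim/
```

## Why cause-specific hazards matter

`polyhazard sim-study` fits all three models to replicate datasets from six
built-in scenarios. When the two causes share a Weibull shape (Model 1) the
all-cause models are correctly specified and everything is nearly unbiased.
When the cause of interest's share of mortality falls rapidly with age
(Model 3), the all-cause Weibull underestimates the study group's 19.8-year
mean survival by around 6 years with essentially zero interval coverage,
while the poly-Weibull stays close to the truth with near-nominal coverage —
the contrast the simulation harness is built to expose.

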