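# gbscure

Bayesian cure-fraction survival analysis for right-censored cohorts, built
around a non-mixture (promotion-time) cure-rate model with a geometric
number of latent competing causes and generalized Birnbaum–Saunders (GBS)
event times.

## Who this is for

Epidemiologists and biostatisticians analysing long-follow-up cohorts — the
motivating case is a breast-cancer registry — where the Kaplan–Meier curve
flattens at a plateau well above zero: a sizeable fraction of patients will
never experience the event. Ordinary survival regression misreads such data;
cure models estimate the cured fraction and the covariate effects on it
separately from the event-time law.

## The model

Each subject carries a latent number of competing causes
*M* ~ Geometric(θ) on {0, 1, 2, …} with P(*M* = *m*) = θ(1 − θ)^*m*, so the
cure probability is P(*M* = 0) = θ. Each cause, if present, has an i.i.d.
event time from the GBS law with CDF

&nbsp;&nbsp;&nbsp;&nbsp;F(t) = Φ( (1/α)[(t/β)^ν − (β/t)^ν] ),&nbsp;&nbsp;α, β, ν > 0,

which reduces to the classical two-parameter Birnbaum–Saunders distribution
at ν = ½. The observed event time is the minimum over causes, giving the
population survival function

&nbsp;&nbsp;&nbsp;&nbsp;S_p(t) = θ / (1 − (1 − θ)·S(t)),

which decreases from 1 to the plateau θ. Covariates act on the cure
fraction through a logistic link, θ_i = expit(x_i′β), so exp(β_j) is a
**cure odds ratio**. Inference is Bayesian: weakly-informative priors,
component-wise adaptive random-walk Metropolis, and 95% highest posterior
density (HPD) intervals for significance. A Kaplan–Meier layer (landmark
survival probabilities, restricted-mean survival time with Greenwood-type
standard errors) covers the descriptive side, and a synthetic-cohort
generator reproduces the registry's statistical structure (covariate
marginals, ≈83% censoring, a 0.46 cure plateau) so the whole pipeline is
testable without the original data. See `docs/methods.md` for details and
assumptions.

## Worked example

```python
from gbscure import (default_table1_config, generate_cohort, run_mcmc,
                     summarize, MCMCConfig)
from gbscure.pipeline import run_km_landmarks

cohort, truth = generate_cohort(default_table1_config(seed=1))
print(f"n = {len(cohort)}, events = {truth['n_events']}, "
      f"censored = {100*truth['censoring_proportion']:.1f}%")

draws = run_mcmc(cohort, covariates=["lvi", "er"],
                 config=MCMCConfig(n_iter=4000, burn_in=1000, thin=3, seed=1))
print(summarize(draws).round(3).to_string())
```

prints

```
n = 3184, events = 556, censored = 82.5%
             mean     sd     p25     p50     p75  exp_mean  hpd_low  hpd_high  significant
parameter
intercept   0.173  0.086   0.113   0.173   0.233     1.189   -0.005     0.327        False
lvi[pos]   -0.886  0.112  -0.958  -0.887  -0.811     0.412   -1.119    -0.662         True
er[pos]     0.395  0.123   0.314   0.393   0.475     1.484    0.170     0.644         True
alpha       0.208  0.066   0.161   0.189   0.243       ...    0.117     0.352         True
beta_scale 16.456  0.135  16.360  16.452  16.545       ...   16.183    16.702         True
nu          0.845  0.263   0.656   0.774   0.983       ...    0.481     1.419         True
```

Reading the table: lymphovascular invasion multiplies the odds of cure by
exp(−0.886) ≈ 0.41 in this two-covariate fit and its 95% HPD interval
excludes zero (significant); positive estrogen-receptor status raises the
cure odds by ≈48%. The last three rows are the shared GBS event-time
parameters (the `exp_mean` column is meaningful for coefficients only).

The same analysis is available from a shell:

```bash
gbscure simulate --seed 1 --out cohort.csv
gbscure descriptives cohort.csv --out table1.tsv
gbscure km cohort.csv --out landmarks.tsv --landmarks 1,5,10,15,20,25
gbscure fit cohort.csv --seed 1 --out table2.tsv
gbscure report --seed 1 --out results/      # everything, incl. plots
```

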