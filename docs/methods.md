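# Methods

This note records the statistical model, the priors and defaults, the
sampler, the descriptive (Kaplan–Meier) conventions, and the design of the
synthetic cohort generator — including what it deliberately does not try to
reproduce.

## 1. Event-time law: generalized Birnbaum–Saunders (GBS)

A positive random variable T follows the GBS law with shape α > 0, scale
β > 0 and power ν > 0 when

    Z = (1/α) · [ (T/β)^ν − (β/T)^ν ]  ~  N(0, 1).

CDF, density and quantile function follow directly:

    F(t) = Φ(z(t)),
    f(t) = φ(z(t)) · (ν/(αt)) · [ (t/β)^ν + (β/t)^ν ],
    Q(q) = β · u^(1/ν),   u = ( α·Φ⁻¹(q) + sqrt(α²·Φ⁻¹(q)² + 4) ) / 2.

Properties used as test oracles: the median equals β; the family is closed
under scaling (β is a true scale parameter); β²/T has the same law as T
(reciprocal symmetry); and at ν = ½ the law is the classical two-parameter
Birnbaum–Saunders (fatigue-life) distribution, for which
`scipy.stats.fatiguelife` is an independent implementation.

Numerics: the CDF/survival use `scipy.special.ndtr`; `log F` and `log S`
use `log_ndtr` so they remain finite far into either tail; the log density
is assembled in the log domain with `logaddexp` for the bracket
(t/β)^ν + (β/t)^ν, so likelihood evaluation does not underflow even where
F(t) or S(t) is exactly 0.0 in floats. The quantile function is the exact
algebraic inversion above (no root finding), and sampling maps standard
normal draws through it.

## 2. Cure model: promotion time with geometric causes

Each subject i carries a latent count of competing causes
M_i ~ Geometric(θ_i) on {0, 1, 2, …}, P(M = m) = θ(1 − θ)^m. Given
M_i = m ≥ 1, the cause times are i.i.d. GBS and the subject's event time is
their minimum; M_i = 0 means the subject is cured (never experiences the
event), with probability P(M_i = 0) = θ_i. Summing the geometric series
gives closed forms for the population (improper) survival and density:

    S_p(t) = θ / (1 − (1 − θ)·S(t)),          S_p(∞) = θ,
    f_p(t) = θ(1 − θ)·f(t) / (1 − (1 − θ)·S(t))²,

with S and f the GBS survival and density. The total event mass is
∫ f_p = 1 − θ, as the cure interpretation requires.

Covariates enter the cure probability through a logistic link,
θ_i = expit(x_i′β), so each exp(β_j) is the multiplicative effect of the
covariate on the **odds of cure**. Categorical covariates are
reference-coded (the last listed level of each variable is the reference;
dummy columns are named `variable[level]`), with an intercept always
included. The GBS parameters (α, β_scale, ν) are shared across subjects.

With right censoring (d_i = 1 event, d_i = 0 censored) the log likelihood
is Σ_i [ d_i · log f_p(t_i) + (1 − d_i) · log S_p(t_i) ], evaluated in the
log domain throughout. Censoring is assumed independent and uninformative.

## 3. Priors and defaults

* Regression coefficients (incl. intercept): N(0, 10²) — weakly
  informative on the logit scale, where effects beyond ±10 are
  practically impossible.
* α, ν: half-normal with sd 5 — covers every shape the law can
  realistically take while discouraging astronomically large values.
* β_scale: half-normal with sd equal to 2 × the median follow-up time of
  the data at hand (resolved when the model is fit), i.e. in the same time
  units as the data; the event-time scale cannot plausibly exceed a few
  multiples of the observed follow-up.

Positive parameters are sampled on the log scale; the log-scale density
includes the Jacobian term (+u for x = e^u), and a quadrature test confirms
the transformed prior integrates to one.

MCMC defaults: 20 000 iterations, 5 000 burn-in, thinning 5 (3 000 retained
draws), initial step 0.1, target acceptance 0.3.

## 4. Sampler

Component-wise adaptive random-walk Metropolis: one Gaussian proposal per
coordinate per sweep. Every 100 iterations **during burn-in only**, each
coordinate's step size is multiplied by exp(clip(rate − 0.3, ±0.5)), where
`rate` is that coordinate's acceptance rate over the window; adaptation is
frozen after burn-in so the post-burn-in chain is a valid Markov chain.
Seeded runs are bit-reproducible, and thinning is pure subsampling of the
same trajectory (tested).

Two implementations target the identical posterior: a generic Python
sampler (`adaptive_metropolis`, any log posterior) and, when `numba` is
importable, a compiled cohort-specific chain that exploits the structure of
the problem — updating one 0/1 dummy coefficient only touches the rows
where that dummy is 1, and the three GBS parameters are recomputed in one
fused pass. A test checks the two samplers' posterior means agree within
Monte Carlo error. Without numba the package falls back to the generic
sampler (slower, same results distributionally).

Reported diagnostics (in `run_log.json` of a full analysis): effective
sample size (via `arviz.ess`), a Geweke z-score comparing the first 10% and
last 50% of the chain with ESS-adjusted variances, and per-coordinate
acceptance rates.

## 5. HPD intervals and the summary table

The 95% HPD interval is the empirical minimum-width interval: among all
windows of m = ⌈0.95·n⌉ consecutive sorted draws, the narrowest (earliest
on ties). Tests compare against exhaustive enumeration. A coefficient is
flagged *significant* when its 95% HPD interval excludes zero. The summary
table reports mean, sd, quartiles, exp(mean) (the cure odds ratio for
coefficient rows), the HPD bounds, and the significance flag.

### Identifiability caveat: (α, ν)

With heavily censored data the GBS shape pair (α, ν) is only weakly
jointly identified — near the median the standardized variable depends on
the pair roughly through ν/α, so a ridge of (α, ν) values fits almost
equally well and their *marginal* posteriors are prior-sensitive. The
regression coefficients and the cure fractions are not affected (verified
by the prior-sensitivity test and the recovery study). Interpret α and ν
jointly, not marginally.

## 6. Kaplan–Meier layer

Product-limit estimator with the standard conventions: at tied times,
events are processed before censorings; the curve is right-continuous;
S(t) = 1 before the first event. Variance by Greenwood's formula. Landmark
survival uses step-function lookup. Restricted mean survival time (RMST)
up to a horizon τ (default: the largest observed time) is the area under
the step curve; its variance is the usual tail-area form
Σ_i A_i² d_i / (n_i (n_i − d_i)) with A_i the area under the curve from t_i
to τ, and the CI is normal-theory ±1.96 se. `lifelines` serves as an
independent oracle in the tests (it is not a runtime dependency).

## 7. Synthetic cohort generator

The generator produces cohorts with the statistical signature of a large
long-follow-up breast-cancer registry, for testing and for parameter
recovery studies:

* **Covariates** — nine categorical variables (age group, surgery type,
  tumor size, nodal status, stage, grade, lymphovascular invasion, ER, PR)
  drawn independently from fixed marginal frequencies (encoded as exact
  counts out of 3 184).
* **Cure structure** — a fixed coefficient vector on the logit-cure scale
  (e.g. lvi[pos] = −1.139, a cure odds ratio of 0.32). The intercept is
  not fixed: it is **calibrated exactly** so the population mean cure
  fraction equals the target 0.46, by enumerating the finite distribution
  of the linear predictor over all covariate combinations and solving
  E[expit(b₀ + η)] = 0.46 with Brent's method (b₀ ≈ −1.828 at the
  defaults).
* **Event times** — M ~ Geometric(θ) causes, each with a GBS time; the
  subject's latent time is the minimum. Default GBS parameters
  (α = 0.25, β_scale = 17, ν = 1, in years) are calibrated so that, under
  the censoring scheme below, the realized censoring proportion is ≈83%
  and the Kaplan–Meier curve of a large cohort reaches its ≈0.46 plateau
  within the observation window.
* **Censoring** — administrative: an independent Uniform(1, 23)-year
  censoring time per subject; observed time is the minimum of latent and
  censoring times.

Each cohort is returned with a `truth` record (intercept, coefficients,
GBS parameters, per-subject cure indicator counts, realized censoring
proportion, mean cure fraction) so recovery can be scored exactly.

**What the generator does not emulate.** Covariates are independent
(a real registry has strong correlations, e.g. stage with nodal status);
there is no accrual pattern beyond the uniform censoring window; and
jointly satisfying ≈83% censoring *and* a visible 0.46 plateau under a
uniform 1–23-year window forces the susceptible event-time mass late into
the window, so the synthetic early landmark survival (1–10 years) is
higher than a real cohort's. The generator matches the quantities the
model estimates — cure structure, censoring burden, plateau — not the
early hazard shape.

## 8. Recovery study and problem sizes

`gbscure.experiments.parameter_recovery` generates cohorts of n = 3 000
from the calibrated truth, fits the full model with default chains, and
reports (a) per-coefficient bias, averaged over replicates, summarized as
the mean absolute bias, and (b) empirical coverage of the 95% HPD
intervals pooled over (coefficient, replicate) pairs. The package's
acceptance script runs 10 replicates; plateau checks use a 50 000-subject
cohort. These sizes balance Monte Carlo error against runtime (the
10-replicate study takes a few minutes with the compiled sampler).

## 9. Limitations

* Covariates act on the cure fraction only; the latency (GBS) part has no
  regression structure.
* The (α, ν) marginal posteriors are prior-sensitive under heavy
  censoring (§5); joint functionals are fine.
* Single-chain inference: diagnostics are within-chain (ESS, Geweke).
  For publication-grade analyses, run multiple seeds and compare.
* The cure interpretation requires follow-up long enough to see the
  plateau; with short follow-up, θ and the GBS scale trade off.
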