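# Methods

## Model

Each subject i has follow-up time tᵢ ≥ 0 (months), event indicator
δᵢ ∈ {0, 1} and a dummy-coded covariate vector xᵢ. The population is a
two-component mixture:

- **Cure (incidence) component.** Membership of the cured fraction is
  Bernoulli with logistic probability π(x) = expit(b₀ + xᵀb). The
  logistic link is the one link under which "odds of being cured" is
  exact and exp(bⱼ) is the cure odds ratio for covariate j, which is how
  the long-term results are reported. π is the probability of *cure*, so
  larger b₀ means a higher plateau.
- **Latency component.** Uncured subjects have a Weibull
  proportional-hazards event time with conditional hazard
  w·γλt^{γ−1}·e^{xᵀβ} given a frailty w. The baseline cumulative hazard
  is parameterised H₀(t) = λt^γ with `shape` γ > 0 and `scale` λ > 0.
- **Frailty.** w ~ Gamma(θ, θ) (shape = rate), fixing E[w] = 1 for
  identifiability; Var(w) = 1/θ. The frailty acts multiplicatively on
  the latency hazard only, never on incidence. Marginalising w
  analytically gives

      S_u(t|x) = (1 + H₀(t)e^{xᵀβ}/θ)^{−θ},
      f_u(t|x) = h₀(t)e^{xᵀβ}(1 + H₀(t)e^{xᵀβ}/θ)^{−θ−1},

  which reduce to the no-frailty Weibull PH model as θ → ∞.

The observed-data log-likelihood marginalises both the frailty and the
latent cure status:

    ℓ = Σ_{δᵢ=1} log[(1 − π(xᵢ)) f_u(tᵢ|xᵢ)]
      + Σ_{δᵢ=0} log[π(xᵢ) + (1 − π(xᵢ)) S_u(tᵢ|xᵢ)].

We deliberately avoid data augmentation (imputing cure status or
frailties): the marginal likelihood is exact, keeps the MCMC state space
small, and makes classical and Bayesian fits target literally the same
function. Events recorded at t = 0 have no density and are rejected at
load time rather than silently shifted. The incidence and latency parts
may use different covariate subsets; the default is the same set in
both.

## Kaplan–Meier plateau diagnosis

Before fitting, the pipeline checks that a cured fraction is actually
visible. `km_estimate` wraps the product-limit estimator (ties handled
events-first); `plateau_cure_fraction` operationalises the usual visual
judgement as:

- cure estimate = KM value at the last observed event time;
- sufficient follow-up ⇔ at least `min_tail_censored` (default 5)
  censored observations lie strictly beyond the last event time.

This is a pragmatic rule, not a formal test (Maller–Zhou style
sufficient-follow-up tests are out of scope). With no events the
estimate defaults to 1 with a warning flag. The pipeline refuses to fit
when the check fails unless explicitly overridden.

## Classical inference

`fit_mle` maximises ℓ over the unconstrained vector
(b₀, b, β, log γ, log λ, log θ) with L-BFGS-B, using 5 starting points
(a data-driven default plus Gaussian jitter, SD 0.5) because mixture
cure likelihoods can be multimodal; the best mode is kept and refined by
a few damped Newton steps with the numerical Hessian, which drives the
score norm below ~1e−6. The default start sets b₀ = logit(KM plateau),
coefficients 0, λ from a censoring-ignored exponential moment match,
γ = θ = 1.

Standard errors come from inverting the numerically differentiated
observed information at the optimum (statsmodels `numdiff`); the delta
method maps them to the natural scale, and Wald intervals for positive
parameters are computed on the log scale and exponentiated, so they are
asymmetric and strictly positive. The standard-normal quantile is used
throughout (no small-sample correction). When the information matrix is
flat in some direction — typical when θ̂ sits at the no-frailty boundary
— the flat parameters get infinite standard errors with a warning
instead of a hard failure, the rest of the covariance being inverted on
the complementary block; `wald_ci` still raises and names the
non-identified parameters if asked for intervals in that state.
`fixed_theta` fits the no-frailty reduction by pinning θ (we use 10⁶)
and dropping it from the parameter vector.

## Bayesian inference

Priors are weakly informative and independent: Normal(0, 10²) on b₀, b
and β, and Normal(0, 10²) on log γ, log λ, log θ. Since the positive
parameters are *sampled on the log scale* and the prior is placed
directly on the log, no Jacobian correction arises. The prior SDs are
configurable (`PriorSpec`); the agreement checks against the MLE use
SD 100.

`mh_sample` runs independent block Gaussian random-walk
Metropolis–Hastings chains on the unconstrained scale. During burn-in
the proposal is adapted: a scalar step multiplier is tuned toward ~30%
acceptance every 100 iterations, and the proposal covariance is
refreshed from the (diagonal-shrunk) empirical covariance of the
second half of the burn-in so far, scaled by 2.38/√p. Shrinking 20%
toward the diagonal matters: short windows overstate correlations and
otherwise leave some eigendirections nearly frozen. All adaptation stops
at the end of burn-in, so the post-burn-in kernel is an exact MH kernel;
acceptance rates are reported for the post-burn-in phase only. Chain c
uses seed `seed + c`, making runs exactly reproducible.

Defaults: 4 chains × 30,000 iterations, 10,000 burn-in, thinning 5.
Summaries (posterior mean, SD, equal-tailed 95% percentile interval) are
computed after burn-in and thinning, on the natural scale (draws of
γ, λ, θ are exponentiated first), so credible intervals automatically
respect each parameter's support. Diagnostics (acceptance rate,
split-chain potential scale reduction, effective sample size via arviz)
warn — never error — on threshold violations (R̂ > 1.05, ESS < 100).
Chains persist as CSV with a JSON metadata sidecar (seed, burn-in,
thinning, priors) for exact re-summarisation.

## Model comparison

With deviance D = −2ℓ and a posterior chain:

- D̄ = posterior mean deviance (evaluated over at most 4000 evenly
  subsampled kept draws),
- p_D = D̄ − D(posterior mean), the Spiegelhalter effective parameter
  count, with the posterior mean taken on the unconstrained scale and
  back-transformed,
- DIC = D̄ + p_D, EAIC = D̄ + 2p, EBIC = D̄ + p·log n.

The classical column of the comparison table uses a plug-in convention,
recorded in the output: D̄ := D(MLE) and p_D = 0, hence DIC = D(MLE),
EAIC = D(MLE) + 2p, EBIC = D(MLE) + p·log n. How such criteria should be
defined for a non-Bayesian fit is genuinely underdetermined; the
convention is labelled rather than hidden. Under these definitions
EBIC ≥ EAIC whenever n ≥ 8, which the implementation treats as an
invariant.

## Synthetic cohorts

`generate_covariates` draws each categorical covariate independently
from its stated marginal frequencies — the registry publishes margins
only, so joint dependence between covariates is *not* emulated, and any
analysis property that hinges on covariate correlation is untested by
construction. `generate_survival` draws cure status Bernoulli(π(x)),
a frailty w ~ Gamma(θ, θ) for the uncured, and an event time by inverse
transform from S(t|w, x) = exp(−w·H₀(t)·e^{xᵀβ}); cured subjects carry
an infinite latent event time. Observed time is the minimum of the event
time, an independent exponential censoring time and an administrative
horizon, and cured subjects are censored exactly like everyone else.

### The registry-like preset

`registry_like_scenario` freezes one scenario emulating a 339-patient
gastric-cancer cohort observed over a 14-year window:

- covariates: chemotherapy (39.8% yes), morphology collapsed to
  neoplasm-vs-malignant (6.8% neoplasm), metastasis (39.5% yes), at the
  cohort's published margins;
- incidence coefficients log(1.53), log(2.99), log(0.41) — the
  published cure odds ratios — and latency coefficients −0.35, −0.98,
  0.40 — the published log hazard ratios;
- b₀ = −0.794, chosen so the marginal cure fraction E[π(x)] = 0.30,
  matching the reported KM plateau of ≈ 0.3;
- Weibull shape 0.83, scale 0.22, frailty θ = 2 (variance 0.5);
- censoring: exponential with rate 0.0191/month, truncated at a
  168-month administrative horizon.

The free constants (b₀, shape, scale, censoring rate) were calibrated
once by simulation so that cohorts reproduce, in expectation, the
cohort-level summaries: event rate ≈ 0.575 (hence censoring ≈ 0.425),
mean observed time ≈ 21.7 months, KM plateau ≈ 0.30, and 3-year survival
within ~0.05 of 0.41. Two published summaries are *not* reproduced under
this censoring mechanism: the observed-time SD (simulated ≈ 33 vs 20.4
reported) and the median survival (≈ 7.5 vs 25.5 months). With a single
truncated-exponential censoring stream these quantities conflict with
the event rate/mean/plateau triple, which was given priority; the real
cohort's censoring process (staggered entry, loss to follow-up) is
unreported and evidently differently shaped. Conclusions that depend on
the fine shape of the censoring distribution should not be read off
this preset.

## Numerical choices

- All survival/density evaluations go through `log1p`/`logaddexp`
  forms, so extreme H₀e^η/θ never overflows the likelihood.
- Quadrature checks of the frailty marginalisation use adaptive
  Gauss–Kronrod integration to 1e−6 absolute tolerance.
- Out-of-support proposals in MCMC score −∞ and are rejected rather
  than raising.
- Degenerate inputs error eagerly and specifically: empty cohorts,
  events at t = 0, all-event or all-censored cohorts (the cure fraction
  is unidentifiable without both), missing CSV values (no imputation
  rule is defined), zero proposal SDs, non-finite targets at the start.

## Problem sizes in the test-suite

The simulation studies behind the test-suite use cohort sizes the
package's own experiments showed to be informative while keeping the
default suite fast: MLE recovery at n = 3390 (10× the registry size),
Bayesian interval coverage at n = 1000 with 4 × 30,000 iterations,
classical/Bayesian agreement at n = 4000, consistency (RMSE shrinkage)
at n ∈ {300, 3000} with 8 replicates, and the DIC direction over 50
replicates at n = 1000 with unit frailty variance, each Bayesian fit
there using short MLE-initialised chains. Known limitations: covariate
independence in the generator (above); the plateau rule is heuristic;
θ is weakly identified at moderate n, where its profile flattens and
the sampler's credible intervals for it are wide — this is a property
of the model, not of the optimiser.
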