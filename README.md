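# curefrail

Mixture cure rate frailty models for right-censored survival data, with
classical (maximum-likelihood) and Bayesian (Metropolis–Hastings)
inference, deviance-based model comparison and a synthetic-cohort
generator.

## Who this is for

Survival analyses of cancers with effective treatment — gastric cancer
registries are the motivating case — routinely contain *long-term
survivors*: patients who will never experience the event of interest.
Their signature is a Kaplan–Meier curve that levels off at a plateau
above zero while censored follow-up continues. Standard proportional
hazards models assume every subject eventually fails and are
misspecified in this setting. Mixture cure models split the population
into a cured fraction and an uncured fraction with its own event-time
distribution, so covariate effects can be reported separately for
*long-term* survival (the odds of being cured) and *short-term* survival
(the hazard among the uncured).

## The model

For a subject with covariates *x*:

- **Incidence (long-term)**: the probability of cure is logistic,
  π(x) = expit(b₀ + xᵀb), so exp(bⱼ) is an odds ratio for being cured.
- **Latency (short-term)**: conditional on a frailty w, the uncured
  hazard is w·h₀(t)·exp(xᵀβ) with Weibull baseline H₀(t) = λ·t^γ
  (`scale` λ, `shape` γ).
- **Frailty**: w ~ Gamma(θ, θ), mean 1 and variance 1/θ, capturing
  unobserved heterogeneity. Marginalising w gives the closed-form
  uncured survival S_u(t|x) = (1 + H₀(t)·e^{xᵀβ}/θ)^{−θ}.
- **Population survival**: S(t|x) = π(x) + (1 − π(x))·S_u(t|x), whose
  t → ∞ limit is the cure fraction — the KM plateau.

Events contribute (1 − π)·f_u(t) to the likelihood and censored records
contribute π + (1 − π)·S_u(t); both the frailty and the latent cure
status are marginalised analytically. The same likelihood is maximised
(L-BFGS with multi-start and a Newton polish; Wald intervals from the
numerically differentiated observed information) or combined with weakly
informative normal priors and sampled by an adaptive random-walk
Metropolis–Hastings algorithm. Fits are compared with DIC, EAIC and
EBIC. See `docs/methods.md` for the full account.

## Worked example

Simulate a registry-like cohort (three binary covariates —
chemotherapy, neoplasm-vs-malignant morphology, metastasis — cure
fraction 0.30, ~57.5% events) and run the whole pipeline:

```
$ curefrail simulate --n 1500 --seed 2 --out cohort.csv
$ curefrail run-all --input cohort.csv --seed 2 --out run \
      --iters 12000 --burn-in 4000 --chains 2
$ cat run/run_log.txt
seed: 2
priors: coefficient_sd=10.0, log_positive_sd=10.0
mcmc: n_iter=12000, burn_in=4000, thin=5, n_chains=2
input: cohort.csv
cohort: n=1500, events=859 (57.3%)
plateau: cure estimate 0.286, 25 censored beyond last event
classical: loglik -3286.39, converged=True
mcmc acceptance rates: 0.206, 0.188
DIC classical 6572.77 (plug-in MLE (pd = 0)); bayesian 6594.02 (pd=10.28)
```

The plateau check reads the cure fraction off the KM curve at the last
event time (0.286 here, true value 0.30) and verifies that censored
follow-up extends beyond it; without that evidence the pipeline refuses
to fit a cure model (`--override-cure-check` forces it).

`run/table2_short_term.csv` holds the latency (short-term) parameters —
for this cohort the Bayesian column gives, e.g., Weibull shape
0.81 (0.73, 0.90), frailty θ 2.11 (0.93, 4.58) against generating values
0.83 and 2.0, and a metastasis log hazard ratio 0.28 (0.06, 0.51):
metastatic patients die faster. `run/table3_long_term.csv` reports the
incidence (long-term) side as cure odds ratios and cure probabilities:

```
    variable     level  odds_ratio  or_low  or_high  cure_probability ...
chemotherapy       yes        1.42    0.99     2.00              0.37
chemotherapy reference        1.00     NaN      NaN              0.30
  morphology  neoplasm        2.77    0.79     5.54              0.52
  metastasis       yes        0.44    0.27     0.63              0.16
```

Chemotherapy raises the odds of cure (OR 1.42), neoplasm morphology
markedly so (2.77), metastasis lowers them (0.44); each row's cure
probability is π(x) at that level with other covariates at reference.

The library mirrors the CLI: `simulate_dataset`, `km_estimate` /
`plateau_cure_fraction`, `fit_mle`, `mh_sample` / `posterior_summary`,
`information_criteria`, and the table builders in
`curefrail.reporting`.

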