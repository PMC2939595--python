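# oabdr — dose-response modelling of overactive-bladder diary endpoints

`oabdr` is a pharmacometric analysis pipeline for pooled fixed-dose trial
programmes in overactive bladder (OAB). It reproduces, on simulated data
with the published design and calibrated effect sizes, a longitudinal
dose-response analysis of an antimuscarinic (fesoterodine 4/8/12 mg vs
placebo, four double-blind 8- or 12-week trials, 2514 subjects): nonlinear
mixed-effects models for diary counts and voided volume, stepwise covariate
selection, a logistic safety model for post-void residual volume (PVR), and
simulation-based posterior predictive checks (PPC).

## The models

For diary counts (micturitions `MICT`, urgency incontinence episodes `UUI`),
the observed count over a `d`-day diary at visit time `t` is Poisson:

    y_ij ~ Poisson( d_ij · B e^{η_i} · (1 − f(t_ij) · (P + D(dose_i))) )

with subject heterogeneity `η_i ~ N(0, ω²)` on the log-baseline, placebo
effect `P` and drug effect `D(dose)` as fractions of baseline, and a shared
exponential onset

    f(t) = 1 − exp(−k t),   k = ln(10)/T90,

so `T90` is the time to 90 % of the asymptotic effect. Mean voided volume
(`MVV`, mL) uses the additive analogue `B e^{η_i} + (P + D(dose)) f(t)` plus
Gaussian residual noise. `D(dose)` can be categorical (one effect per dose
level), linear, square-root or Emax.

Marginal likelihoods integrate `η` out by the Laplace approximation (exact
for the linear-Gaussian case), maximized over transformed parameters; the
objective function value (OFV) is −2 log-likelihood, and ΔOFV between
nested models is χ²-referenced: covariates enter stepwise at p < 0.01 and
are deleted backward at p ≥ 0.001. Individual `η̂_i` are empirical-Bayes
(conditional-mode) estimates. PVR safety is one Bernoulli per subject —
"PVR exceeded 100 mL at any time" — modelled by logistic regression on
baseline PVR, dose (linear in mg vs √mg compared by AIC), sex, age > 70
and the dose × sex / dose × age interactions.

## Worked example

```sh
oabdr simulate --seed 1 --out data.csv
oabdr fit --data data.csv --endpoint MICT --out fit_mict.json
oabdr predict --fit fit_mict.json --baseline 11 --doses 0,4,8
```

prints

```
endpoint MICT, baseline 11.0, day 84
   0 mg: -1.23
   4 mg: -1.70
   8 mg: -2.27
```

i.e. after fitting the Poisson mixed model to the simulated pooled
programme, a typical patient with 11 micturitions/24 h at baseline is
predicted to void 1.2 fewer times per day after 12 weeks on placebo, 1.7
fewer on 4 mg and 2.3 fewer on 8 mg — recovering the calibrated truth
(−1.2 / −1.7 / −2.2). `oabdr report --seed 1 --outdir run/` runs the whole
pipeline (all three efficacy endpoints, PVR fit, PPCs) and writes
`report.md` with the week-12 prediction table and the PVR exceedance
summary; `oabdr --help` lists the remaining verbs (`stepwise`, `pvr`,
`ppc`).

The library API mirrors the CLI: `simulate_trial`, `fit`, `stepwise`,
`fit_logistic`, `run_ppc`, all operating on a long-format
`PooledDataset` (CSV schema documented in `oabdr.trial_data`).

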