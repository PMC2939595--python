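# Methods

## Scope and data model

The package analyses pooled longitudinal data from a fixed-dose OAB trial
programme: four double-blind studies (two 8-week phase II, two 12-week
phase III) randomizing 2514 subjects to placebo or 4/8/12 mg, with the
12 mg arms present only in phase II. All stages exchange a long-format
table (`PooledDataset`) with one row per visit-level observation: diary
counts are stored as the raw sum over the diary window so the Poisson
likelihood is exact; per-24 h rates are derived quantities. Time is days
since randomization (week 12 = day 84). Baseline PVR must lie in
[0, 100) mL, mirroring the trials' exclusion criterion.

Because the source trials are not publicly deposited, the pipeline runs on
synthetic programmes whose generating parameters are calibrated to the
published typical-patient effects; the estimation layer never sees the
truth, so recovering those effects end to end is the package's principal
correctness check.

## Structural model

For counts, the subject-level visit mean is

    mu_ij = diary_days_ij * B * exp(eta_i) * (1 - f(t_ij) * (P + D(dose_i)))

with log-normal between-subject baseline heterogeneity
`eta_i ~ N(0, omega^2)`, placebo effect `P` and drug effect `D(dose)` as
fractions of baseline, and exponential onset `f(t) = 1 - exp(-ln(10) t /
T90)`. MVV is additive in mL with Gaussian residual noise. Conventions
and open choices:

* **T90.** "Peak response at about day X" is operationalized as the time
  to 90 % of the asymptotic effect (`k = ln(10)/T90`): a smooth
  exponential has no finite peak, and T90 is the standard near-maximum
  convention. Defaults: 27 d (micturitions), 18 d (MVV), 120 d (UUI — the
  response has visibly not plateaued by day 84; with T90 = 120 d the
  day-84 onset fraction is 0.80 and still rising).
* **One onset per endpoint.** Placebo and drug effects share `f(t)`.
  Separate onset constants per component are not identified by the
  printed results; the config accepts per-endpoint overrides but the
  default is a single T90.
* **Dose models.** Categorical (saturated), linear, square-root and Emax.
  The truth calibration uses linear-in-dose effects for micturitions
  (0.5/11 per 4 mg step beyond a 1.2/11 placebo fraction) and MVV
  (+14.2 mL per 4 mg beyond +9.7 mL placebo), and per-dose effects for
  UUI, whose 12 mg value comes from the Emax curve solved through the 4
  and 8 mg points (closed form; ED50 = 34 mg) — two printed points are the
  only anchors, so no third value is invented.
* **UUI rescaling.** The published UUI changes are week-12 values of a
  response that has not plateaued, so the asymptotic truth fractions are
  the printed day-84 fractions divided by f(84) = 0.80.

## Synthetic programme

`default_design()` reproduces the published subject counts exactly
(768/759/762/225 by dose; 727/173/816/798 by study). Visit schedules are
not printed anywhere, so they are declared, not inferred: phase III
{0, 14, 28, 56, 84} d, phase II {0, 14, 28, 56} d, 3-day diaries
throughout. Demographics follow the trial-typical OAB population (80 %
female, age N(65, 10), BMI N(27, 4.5)); baseline PVR is 100·Beta(1.2, 4.8)
(mean 20 mL, support [0, 100)). Between-subject variances default to
omega^2 = 0.09 (MICT), 0.36 (UUI), 0.04 (MVV, log scale) — plausible trial
heterogeneity treated as configuration, not as claims. The MVV residual SD
is 35 mL and its baseline 156 mL; only the *changes* are calibrated, so
any positive baseline works. Dropout is not simulated. Counts are plain
Poisson (no zero inflation): entry criteria guarantee positive baselines.

PVR is reduced to one Bernoulli per subject ("ever exceeded 100 mL"),
matching the modelling target of the analysis rather than longitudinal
PVR. The truth logit is dominated by baseline PVR (0.045 per mL), with
dose slopes concentrated in men (+0.10 per mg) and subjects over 70
(+0.06 per mg) and a small common slope (0.02 per mg); the intercept
(−4.4179) was root-found once by large-sample simulation
(`calibrate_pvr_intercept`) so the marginal exceedance rate is 6.8 %, then
frozen. Coefficient magnitudes other than the intercept are package
choices: the source analysis prints none.

What the generator does *not* emulate: dropout and missed visits,
overdispersion beyond the log-normal frailty, serial correlation of
residuals, covariate effects on efficacy (unless constructed explicitly,
as the covariate-selection tests do by stratified simulation), seasonal or
site effects. Passing tests therefore demonstrate correct inference under
the stated model, not robustness to misspecification.

## Estimation

One random effect per subject (baseline), integrated out by the Laplace
approximation — mode plus curvature of the conditional density. For the
proportional Poisson model the visit means factor as `c_ij e^eta`, so a
subject's conditional log-likelihood depends on the data only through
`sum(y)`, `sum(c)` and `sum(y log c)`, and the inner mode is a scalar
Newton solve (tolerance 1e-8, analytic first and second derivatives,
vectorized across all subjects, warm-started between outer iterations).
For the Gaussian endpoint with additive `eta` the Laplace integral is
exact; with the default log-normal baseline a damped Newton with step
halving finds the mode. A 64-node adaptive Gauss–Hermite quadrature
implementation serves as an independent oracle: on trial-like fuzzed
subjects the Laplace −2LL agrees within 1e-2 (1e-3 at omega^2 ≈ 0.09).

The outer problem maximizes total marginal likelihood over transformed
parameters (log for positive quantities, logit for the placebo fraction)
with L-BFGS-B, falling back to Nelder–Mead when line search fails;
inadmissible regions (any non-positive rate at an observed time) return a
large penalty increasing in the violation. Standard errors come from the
numerical Hessian of the OFV at the optimum (covariance = 2·H⁻¹ on the
transformed scale); CV% = 100·SE/|estimate| on the natural scale by the
delta method. The count likelihood is implemented for the proportional
effect scale — the final form of the count models — while the structural
layer supports both scales for prediction.

FOCE-style linearization is deliberately not implemented: one well-tested
integral approximation with a quadrature oracle is preferred to two
half-tested ones. Estimates are typical-subject parameters; note that the
*population mean* day-84 change under log-normal heterogeneity is
exp(omega^2/2) times the typical change, which is why generator-level
tests compare arm means against the heterogeneity-adjusted expectation
while fit-level tests compare typical predictions against the calibration.

## Covariate selection

Forward steps add, among candidates reaching p < 0.01 (LRT, df 1), the one
with the largest OFV drop, ties broken by candidate order; backward steps
delete the covariate whose removal test has the largest p-value when that
p ≥ 0.001. Candidates default to age, sex, BMI and baseline endpoint
value; continuous covariates enter linearly on the response parameter,
centered at reference values (age 65, BMI 27) and scaled (per decade, per
5 BMI units) for conditioning; binary covariates are 0/1 shifts. The
forward-inclusion type-I error of a pure-noise covariate is verified by
simulation to sit near the nominal 1 %. Which covariates the original
efficacy models retained is not printed; the module reports its own trail
without claiming to match.

## PVR exceedance model

Maximum-likelihood logistic regression (statsmodels binomial GLM/IRLS)
with single-covariate perfect-separation detection before fitting. Dose
enters linearly in mg or as sqrt(mg); both are fitted and compared by AIC
= 2k − 2 log L, keeping the linear model unless sqrt wins by more than 2
points — a marginal AIC advantage does not displace the simpler form.
150 and 200 mL thresholds are descriptive only (too few exceeders to
model). Subgroup summaries (sex × age-70 × dose) report observed rates
against 10/50/90 % quantiles of parametric re-simulations of every
subject's fitted Bernoulli outcome.

## Posterior predictive check

Replicate programmes are simulated from the fitted model — by default 1000
replicates, each drawing a parameter vector from the asymptotic normal of
the estimates on the transformed scale (redrawing inadmissible vectors, at
most 10 times) — and summarized by the arm-level mean change from baseline
per 24 h at each visit, the same statistic computed from the observed
data. A cell is "inside" when the observed value lies within the
replicate 10–90 % band. With ~15 correlated cells, an exactly correct
model still leaves some cell outside an 80 % band with high probability,
so calibration is judged by the *fraction* of inside cells (near or above
0.8 when parameter uncertainty widens the bands), while the strict
all-cells-inside flag is reported alongside. Sensitivity is real: zeroing
the drug effect and refitting forces the placebo parameter to absorb a
pooled average, and the PPC then misses most arms at once (inside fraction
drops to ~0.3).

## Numerical and testing choices

* Determinism: every stochastic step takes an integer seed;
  `numpy.random.SeedSequence` spawning keeps endpoint streams independent;
  identical seeds give byte-identical datasets and reports.
* Degenerate inputs: omega^2 below 1e-10 switches to the exact
  zero-heterogeneity likelihood; empty designs yield empty tables; a
  non-positive rate during generation names the offending subject.
* Test problem sizes are scaled to keep the suite quick while leaving
  Monte-Carlo margins honest: full 2514-subject fits for the headline
  recovery checks (~1 s per endpoint fit), ~400-subject replicates for
  the 200-trial type-I-error simulation, a quarter-scale programme and
  150 replicates per seed for the 20-seed PPC calibration.
* The CLI is a thin layer; all numbers in a report are traceable to the
  serialized stage outputs (`fit_*.json`, `report.json`).

## Known limitations

Exposure (concentration)–response is out of scope — dose, not
pharmacokinetics, drives the models. Only one random effect (baseline) is
estimated; random effects on the response parameter are a config
extension of the generator but not of the fitter. The Poisson fit does
not cover the additive effect scale. OFV values are comparable only
within this implementation (they include all data-dependent constants but
no software-specific offsets of other estimators). Missing covariates are
disallowed; complete cases are assumed throughout.
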