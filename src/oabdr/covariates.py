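"""Stepwise forward/backward covariate selection by likelihood-ratio test.

Candidate covariates enter as linear shifts on the treatment-response
parameter ``P`` (continuous ones centered at reference values — age 65,
BMI 27 — binary ones as 0/1 indicators).  Forward inclusion requires
p < 0.01; backward deletion removes a covariate only when its removal test
gives p >= 0.001.  Ties are broken by candidate order, so a trail is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .nlme import FitResult, fit
from .structural import StructuralSpec
from .trial_data import PooledDataset

FORWARD_ALPHA = 0.01
BACKWARD_ALPHA = 0.001

DEFAULT_CANDIDATES = ("age", "sex", "bmi", "base")


@dataclass
class CovariateStep:
    action: str                   # add | delete | stop
    covariate: str | None
    parameter: str
    delta_ofv: float | None
    df: int | None
    p_value: float | None
    accepted: bool
    diagnostics: str = ""


def _refit(base: FitResult, data: PooledDataset,
           covariates: tuple[str, ...]) -> FitResult:
    """Fit the base structural model with the given covariate set, warm
    starting from the base estimates (new coefficients at 0)."""
    init = base.estimates.copy_with(
        **{f"beta_{c}": base.estimates.values.get(f"beta_{c}", 0.0)
           for c in covariates})
    return fit(data, base.spec, init, endpoint=base.endpoint,
               covariates=covariates, fixed=base.fixed,
               eta_model=base.eta_model, compute_cv=False)


def forward_step(base: FitResult, data: PooledDataset,
                 candidates: list[str]) -> tuple[CovariateStep, FitResult]:
    """Try adding each candidate; accept the largest OFV drop with p < 0.01."""
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if not base.converged:
        raise ValueError("base fit has not converged")
    best = None
    failures = []
    for cand in candidates:
        try:
            trial = _refit(base, data, base.covariates + (cand,))
        except Exception as err:  # candidate fit failed; note and continue
            failures.append(f"{cand}: {err}")
            continue
        if not trial.converged:
            failures.append(f"{cand}: did not converge")
            continue
        delta = max(0.0, base.ofv - trial.ofv)
        p = float(chi2.sf(delta, 1))
        if p < FORWARD_ALPHA and (best is None or delta > best[1]):
            best = (cand, delta, p, trial)
    if best is None:
        return (CovariateStep("stop", None, "P", None, None, None, False,
                              diagnostics="; ".join(failures)), base)
    cand, delta, p, trial = best
    return (CovariateStep("add", cand, "P", delta, 1, p, True), trial)


def backward_step(full: FitResult,
                  data: PooledDataset) -> tuple[CovariateStep, FitResult]:
    """Drop the included covariate whose removal test has the largest
    p-value, provided that p >= 0.001; otherwise stop."""
    if not full.covariates:
        raise ValueError("full model has no covariates to delete")
    worst = None
    for cand in full.covariates:
        reduced_covs = tuple(c for c in full.covariates if c != cand)
        reduced = _refit(full, data, reduced_covs)
        delta = max(0.0, reduced.ofv - full.ofv)
        p = float(chi2.sf(delta, 1))
        if worst is None or p > worst[2]:
            worst = (cand, delta, p, reduced)
    cand, delta, p, reduced = worst
    if p >= BACKWARD_ALPHA:
        return (CovariateStep("delete", cand, "P", delta, 1, p, True), reduced)
    return (CovariateStep("stop", None, "P", delta, 1, p, False), full)


def stepwise(data: PooledDataset, spec: StructuralSpec,
             candidates: tuple[str, ...] = DEFAULT_CANDIDATES, *,
             endpoint: str,
             fixed: dict[str, float] | None = None,
             eta_model: str = "log",
             ) -> tuple[FitResult, list[CovariateStep]]:
    """Forward inclusion until no candidate reaches p < 0.01, then backward
    deletion until every remaining covariate is significant at p < 0.001."""
    base = fit(data, spec, endpoint=endpoint, fixed=fixed,
               eta_model=eta_model, compute_cv=False)
    trail: list[CovariateStep] = []
    current = base
    remaining = list(candidates)
    while remaining:
        step, current = forward_step(current, data, remaining)
        trail.append(step)
        if step.action != "add":
            break
        remaining.remove(step.covariate)
    while current.covariates:
        step, current = backward_step(current, data)
        trail.append(step)
        if step.action != "delete":
            break
    # refit the final model with standard errors
    if current.covariates or current is not base:
        final = fit(data, spec, current.estimates, endpoint=endpoint,
                    covariates=current.covariates, fixed=fixed,
                    eta_model=eta_model)
    else:
        final = fit(data, spec, base.estimates, endpoint=endpoint,
                    fixed=fixed, eta_model=eta_model)
    return final, trail
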