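"""Deterministic structural model functions shared by the generator,
likelihood and prediction layers.

The treatment-effect time course is an exponential onset
``f(t) = 1 - exp(-k t)`` with ``k = ln(10) / T90``, so ``T90`` is the time to
90 % of the asymptotic effect (a smooth exponential has no finite peak; T90 is
the near-maximum convention used for "time to peak response").

Dose enters through one of four dose models (``categorical``, ``linear``,
``emax``, ``sqrt``); the placebo effect ``P`` and the drug effect ``D(dose)``
share the onset.  On the ``proportional`` scale the effect multiplies the
subject's baseline rate (count endpoints); on the ``additive`` scale it adds
to the baseline value in natural units (mean voided volume, mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

LN10 = math.log(10.0)

EFFECT_SCALES = ("proportional", "additive")
DOSE_MODELS = ("categorical", "linear", "emax", "sqrt")
ONSETS = ("exponential", "none")
FAMILIES = ("poisson_count", "gaussian")


class DomainError(ValueError):
    """Argument outside the model's domain (negative time, rate <= 0, ...)."""


@dataclass(frozen=True)
class StructuralSpec:
    """Which structural form is in play for one endpoint model."""

    effect_scale: str = "proportional"
    dose_model: str = "categorical"
    onset: str = "exponential"
    endpoint_family: str = "poisson_count"

    def __post_init__(self):
        if self.effect_scale not in EFFECT_SCALES:
            raise ValueError(f"effect_scale must be one of {EFFECT_SCALES}")
        if self.dose_model not in DOSE_MODELS:
            raise ValueError(f"dose_model must be one of {DOSE_MODELS}")
        if self.onset not in ONSETS:
            raise ValueError(f"onset must be one of {ONSETS}")
        if self.endpoint_family not in FAMILIES:
            raise ValueError(f"endpoint_family must be one of {FAMILIES}")


@dataclass
class StructuralParams:
    """Fixed-effect parameters of one endpoint model.

    placebo
        Placebo asymptotic effect: fraction of baseline (proportional scale)
        or mL (additive scale).
    dose_params
        Dose-model parameters: ``{"by_dose": {mg: effect}}`` (categorical,
        dose 0 implicit), ``{"slope": per-mg}`` (linear), ``{"slope":
        per-sqrt-mg}`` (sqrt) or ``{"emax": ..., "ed50": mg}`` (emax).
    t90
        Time to 90 % of the asymptotic effect, days.
    """

    placebo: float
    dose_params: dict = field(default_factory=dict)
    t90: float = 27.0


def onset_fraction(t, t90):
    """Fraction of the asymptotic effect reached at time ``t`` (days).

    ``1 - exp(-(ln 10 / t90) * t)``; 0 at baseline, 0.9 at ``t = t90``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    if t90 <= 0:
        raise DomainError("t90 must be > 0")
    out = -np.expm1(-(LN10 / t90) * t)
    return float(out) if out.ndim == 0 else out


def solve_emax(d1: float, e1: float, d2: float, e2: float) -> tuple[float, float]:
    """Solve ``E(d) = Emax d / (ED50 + d)`` through two (dose, effect) points.

    Raises :class:`DomainError` when the two points do not determine a proper
    Emax curve (non-concave pair, equal doses, non-positive ED50).
    """
    if d1 <= 0 or d2 <= 0 or d1 == d2 or e1 <= 0 or e2 <= 0:
        raise DomainError("need two distinct positive (dose, effect) points")
    # e2/e1 = d2 (ED50 + d1) / (d1 (ED50 + d2))
    r = e2 / e1
    denom = r * d1 - d2
    if denom >= 0:
        raise DomainError("points are not consistent with a saturating Emax curve")
    ed50 = (d2 * d1 - r * d1 * d2) / denom
    if ed50 <= 0:
        raise DomainError("degenerate Emax solve (ED50 <= 0)")
    emax = e1 * (ed50 + d1) / d1
    return emax, ed50


def dose_effect(dose_mg, dose_params: dict, dose_model: str):
    """Asymptotic drug effect at ``dose_mg`` (0 at dose 0 for every model)."""
    if dose_model not in DOSE_MODELS:
        raise ValueError(f"unknown dose_model {dose_model!r}")
    d = np.asarray(dose_mg, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be >= 0")
    if dose_model == "categorical":
        by_dose = dict(dose_params["by_dose"])
        by_dose.setdefault(0, 0.0)
        try:
            out = np.vectorize(lambda x: float(by_dose[int(x)]))(d)
        except KeyError as err:
            raise DomainError(f"dose {err.args[0]} mg not in categorical map") from None
    elif dose_model == "linear":
        out = dose_params["slope"] * d
    elif dose_model == "sqrt":
        out = dose_params["slope"] * np.sqrt(d)
    else:  # emax
        out = dose_params["emax"] * d / (dose_params["ed50"] + d)
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def _onset(t, params: StructuralParams, spec: StructuralSpec):
    if spec.onset == "exponential":
        return onset_fraction(t, params.t90)
    t = np.asarray(t, dtype=float)
    out = (t > 0).astype(float)
    return float(out) if out.ndim == 0 else out


def total_effect(dose_mg, t, params: StructuralParams, spec: StructuralSpec):
    """(P + D(dose)) * f(t): signed magnitude of the combined effect."""
    f = _onset(t, params, spec)
    d = dose_effect(dose_mg, params.dose_params, spec.dose_model)
    return (params.placebo + d) * f


def typical_change(baseline, dose_mg, t, params: StructuralParams,
                   spec: StructuralSpec):
    """Model-predicted change from baseline for the typical patient.

    Sign convention: diary counts decrease under treatment (proportional
    scale returns ``-baseline * (P + D) * f(t)``), mean voided volume
    increases (additive scale returns ``+(P + D) * f(t)``).
    """
    eff = total_effect(dose_mg, t, params, spec)
    if spec.effect_scale == "proportional":
        return -np.asarray(baseline, dtype=float) * eff
    return eff + 0.0 * np.asarray(baseline, dtype=float)


def subject_rate(baseline_i, dose_mg, t, params: StructuralParams,
                 spec: StructuralSpec):
    """Individual expected value per 24 h (Poisson mean for counts).

    Raises :class:`DomainError` when the parameters drive the rate to <= 0;
    the likelihood layer treats that as an inadmissible parameter step.
    """
    b = np.asarray(baseline_i, dtype=float)
    if np.any(b <= 0):
        raise DomainError("baseline must be > 0")
    eff = total_effect(dose_mg, t, params, spec)
    if spec.effect_scale == "proportional":
        rate = b * (1.0 - eff)
    else:
        rate = b + eff
    if np.any(np.asarray(rate) <= 0):
        raise DomainError("rate <= 0: inadmissible effect parameters")
    return float(rate) if np.ndim(rate) == 0 else rate
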