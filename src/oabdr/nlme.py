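"""Maximum-likelihood estimation of the longitudinal mixed-effects models.

One random effect per subject: a log-normal perturbation ``exp(eta)``,
``eta ~ N(0, omega^2)``, on the subject's baseline level.  The marginal
likelihood integrates eta out; for Poisson diary counts this integral has no
closed form and is approximated by Laplace's method (mode of the conditional
density plus curvature correction) — the standard count-data approach in
population modelling.  For the Gaussian endpoint with an additive random
effect the Laplace approximation is exact.

The objective function value (OFV) is -2 x log marginal likelihood;
differences in OFV between nested models are chi-square distributed and
drive covariate selection.  Individual empirical-Bayes estimates (EBEs,
"POSTHOC") are the conditional modes eta_hat.

Poisson structure exploited throughout: with a proportional treatment
effect the subject's visit means factor as ``c_ij * exp(eta)`` where
``c_ij = diary_days * B * (1 - f(t_ij) (P_i + D_i))``, so each subject's
conditional log-likelihood depends on the data only through
``S1 = sum(y)``, ``C = sum(c)``, ``T = sum(y log c)`` and the inner Newton
iteration is a scalar root solve, vectorized across subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .structural import StructuralParams, StructuralSpec, onset_fraction, typical_change
from .trial_data import PooledDataset

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1.0e7
_OMEGA_TINY = 1.0e-10

#: reference values at which continuous covariates are centered
COVARIATE_REFERENCES = {"age": 65.0, "bmi": 27.0}


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter sets and transforms
# ---------------------------------------------------------------------------

def _to_unconstrained(value: float, transform: str) -> float:
    if transform == "log":
        return math.log(value)
    if transform == "logit":
        return math.log(value / (1.0 - value))
    return value


def _from_unconstrained(z: float, transform: str) -> float:
    if transform == "log":
        return math.exp(z)
    if transform == "logit":
        return 1.0 / (1.0 + math.exp(-z))
    return z


def _dnatural_dz(theta: float, transform: str) -> float:
    if transform == "log":
        return theta
    if transform == "logit":
        return theta * (1.0 - theta)
    return 1.0


@dataclass
class ParameterSet:
    """Named natural-scale parameter values plus their transform tags.

    Transforms (``log`` for positive, ``logit`` for (0,1), ``identity``)
    define the unconstrained scale on which optimization and standard
    errors operate.
    """

    values: dict[str, float]
    transforms: dict[str, str] = field(default_factory=dict)

    def transform_of(self, name: str) -> str:
        return self.transforms.get(name, "identity")

    def copy_with(self, **updates) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(values=vals, transforms=dict(self.transforms))


@dataclass
class FitResult:
    estimates: ParameterSet
    ofv: float
    cv_percent: dict[str, float] | None
    ebe: pd.Series
    converged: bool
    n_subjects: int
    n_obs: int
    spec: StructuralSpec
    endpoint: str
    free_names: list[str]
    fixed: dict[str, float]
    covariates: tuple[str, ...]
    cov_unconstrained: np.ndarray | None
    eta_model: str = "log"
    message: str = ""

    def structural_params(self) -> StructuralParams:
        return _structural_params(self.estimates.values, self.spec)

    def typical_change(self, baseline, dose_mg, t):
        """Typical-patient predicted change from baseline at (dose, t)."""
        return typical_change(baseline, dose_mg, t,
                              self.structural_params(), self.spec)

    def se_unconstrained(self) -> dict[str, float] | None:
        if self.cov_unconstrained is None:
            return None
        se = np.sqrt(np.clip(np.diag(self.cov_unconstrained), 0.0, None))
        return dict(zip(self.free_names, se))


def _dose_param_names(spec: StructuralSpec, doses_present) -> list[str]:
    if spec.dose_model == "categorical":
        return [f"D{int(d)}" for d in sorted(doses_present) if d > 0]
    if spec.dose_model in ("linear", "sqrt"):
        return ["slope"]
    return ["emax", "ed50"]


def _structural_params(values: dict[str, float],
                       spec: StructuralSpec) -> StructuralParams:
    if spec.dose_model == "categorical":
        by_dose = {int(k[1:]): v for k, v in values.items()
                   if k.startswith("D") and k[1:].isdigit()}
        dose_params = {"by_dose": by_dose}
    elif spec.dose_model in ("linear", "sqrt"):
        dose_params = {"slope": values["slope"]}
    else:
        dose_params = {"emax": values["emax"], "ed50": values["ed50"]}
    return StructuralParams(placebo=values["P"], dose_params=dose_params,
                            t90=values["T90"])


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

@dataclass
class EndpointData:
    """Padded per-subject arrays for one endpoint."""

    subj: np.ndarray          # (n,) subject ids
    y: np.ndarray             # (n, m) observed values
    t: np.ndarray             # (n, m) days
    ddays: np.ndarray         # (n, m) diary lengths (1.0 for mL endpoints)
    mask: np.ndarray          # (n, m) observation present
    dose: np.ndarray          # (n,)
    X: np.ndarray             # (n, k) covariate design (k may be 0)
    endpoint: str = ""

    @property
    def n_subjects(self) -> int:
        return len(self.subj)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def covariate_vector(name: str, subject_table: pd.DataFrame,
                     endpoint: str) -> np.ndarray:
    """Per-subject covariate column for an effect on the placebo+drug
    response: centered/scaled continuous values or 0/1 indicators."""
    if name == "age":
        return (subject_table["AGE"].to_numpy(float) - COVARIATE_REFERENCES["age"]) / 10.0
    if name == "sex":
        return (subject_table["SEX"] == "M").to_numpy(float)
    if name == "bmi":
        return (subject_table["BMI"].to_numpy(float) - COVARIATE_REFERENCES["bmi"]) / 5.0
    if name == "base":
        col = subject_table[f"BASE_{endpoint}"].to_numpy(float)
        return col / col.mean() - 1.0
    raise ValueError(f"unknown covariate {name!r}")


def build_endpoint_data(data: PooledDataset, endpoint: str,
                        covariates: tuple[str, ...] = ()) -> EndpointData:
    df = data.endpoint_frame(endpoint)
    if df.empty:
        raise FitError(f"no observations for endpoint {endpoint}")
    subj_ids = df["SUBJ"].drop_duplicates().to_numpy()
    index = pd.Index(subj_ids)
    groups = df.groupby("SUBJ", sort=False)
    m = int(groups.size().max())
    n = len(subj_ids)
    y = np.zeros((n, m))
    t = np.zeros((n, m))
    dd = np.ones((n, m))
    mask = np.zeros((n, m), dtype=bool)
    dose = np.zeros(n)
    for i, (subj, grp) in enumerate(groups):
        k = len(grp)
        y[i, :k] = grp["DV"].to_numpy(float)
        t[i, :k] = grp["TIME_D"].to_numpy(float)
        ddv = pd.to_numeric(grp["DIARY_D"], errors="coerce").to_numpy(float)
        dd[i, :k] = np.where(np.isnan(ddv), 1.0, ddv)
        mask[i, :k] = True
        dose[i] = grp["DOSE_MG"].iloc[0]
    subj_tab = data.subject_table().loc[index]
    X = (np.column_stack([covariate_vector(c, subj_tab, endpoint)
                          for c in covariates])
         if covariates else np.zeros((n, 0)))
    return EndpointData(subj=subj_ids, y=y, t=t, ddays=dd, mask=mask,
                        dose=dose, X=X, endpoint=endpoint)


# ---------------------------------------------------------------------------
# per-subject marginal likelihood: Poisson (Laplace + AGQ oracle)
# ---------------------------------------------------------------------------

def _poisson_eta_hat(S1, C, omega2, eta0=None, tol=1e-8, maxiter=100):
    """Vectorized root of S1 - C e^eta - eta/omega2 = 0 (conditional mode)."""
    S1 = np.atleast_1d(np.asarray(S1, float))
    C = np.atleast_1d(np.asarray(C, float))
    eta = (np.log((S1 + 0.5) / (C + 0.5)).clip(-4.0, 4.0)
           if eta0 is None else np.atleast_1d(np.array(eta0, float)))
    for _ in range(maxiter):
        e = C * np.exp(eta)
        r = S1 - e - eta / omega2
        step = np.clip(r / (e + 1.0 / omega2), -4.0, 4.0)
        eta = eta + step
        if np.max(np.abs(r)) < tol:
            break
    return eta


def poisson_subject_nll_laplace(y, c, omega2) -> float:
    """-2 log marginal likelihood of one Poisson subject, Laplace method.

    ``c`` are the subject's visit means at eta = 0; the model mean is
    ``c * exp(eta)`` with ``eta ~ N(0, omega2)``.
    """
    y = np.asarray(y, float)
    c = np.asarray(c, float)
    S1, C = y.sum(), c.sum()
    T = float(np.sum(y * np.log(c)))
    G = float(np.sum(gammaln(y + 1.0)))
    if omega2 < _OMEGA_TINY:
        return -2.0 * (T - C - G)
    eta = float(_poisson_eta_hat(S1, C, omega2)[0])
    H = C * math.exp(eta) + 1.0 / omega2
    logm = (T + eta * S1 - C * math.exp(eta) - G
            - eta * eta / (2.0 * omega2) - 0.5 * math.log(omega2)
            - 0.5 * math.log(H))
    return -2.0 * logm


def poisson_subject_nll_agq(y, c, omega2, n_nodes: int = 64) -> float:
    """Adaptive Gauss-Hermite oracle for the same quantity (reference
    implementation; independent of the Laplace path beyond the shared mode
    used for centering)."""
    y = np.asarray(y, float)
    c = np.asarray(c, float)
    S1, C = y.sum(), c.sum()
    T = float(np.sum(y * np.log(c)))
    G = float(np.sum(gammaln(y + 1.0)))
    if omega2 < _OMEGA_TINY:
        return -2.0 * (T - C - G)
    eta_hat = float(_poisson_eta_hat(S1, C, omega2)[0])
    s = 1.0 / math.sqrt(C * math.exp(eta_hat) + 1.0 / omega2)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = eta_hat + math.sqrt(2.0) * s * x
    h = (T + nodes * S1 - C * np.exp(nodes) - G
         - nodes ** 2 / (2.0 * omega2) - 0.5 * math.log(2.0 * math.pi * omega2))
    logm = (math.log(math.sqrt(2.0) * s)
            + logsumexp(h + x ** 2 + np.log(w)))
    return -2.0 * logm


# ---------------------------------------------------------------------------
# model objects
# ---------------------------------------------------------------------------

class _MixedModel:
    """Internal: maps an unconstrained parameter vector to the total OFV."""

    def __init__(self, data: EndpointData, spec: StructuralSpec,
                 covariates: tuple[str, ...] = (),
                 fixed: dict[str, float] | None = None,
                 eta_model: str = "log"):
        if spec.endpoint_family == "poisson_count" and spec.effect_scale != "proportional":
            raise NotImplementedError(
                "the count likelihood is implemented for the proportional "
                "effect scale (the final count models' form)")
        if eta_model not in ("log", "linear"):
            raise ValueError("eta_model must be 'log' or 'linear'")
        self.data = data
        self.spec = spec
        self.covariates = tuple(covariates)
        self.fixed = dict(fixed or {})
        self.eta_model = eta_model
        self.is_poisson = spec.endpoint_family == "poisson_count"
        doses = sorted(set(int(d) for d in data.dose))
        names = ["B", "P"] + _dose_param_names(spec, doses) + ["T90", "omega2"]
        if not self.is_poisson:
            names.append("sigma")
        names += [f"beta_{c}" for c in self.covariates]
        self.all_names = names
        self.free_names = [n for n in names if n not in self.fixed]
        self.transforms = self._default_transforms()
        self._eta_warm: np.ndarray | None = None
        # data-dependent caches
        self._S1 = np.sum(data.y * data.mask, axis=1)
        self._G = np.sum(gammaln(data.y + 1.0) * data.mask, axis=1)
        self._nobs = data.mask.sum(axis=1).astype(float)

    def _default_transforms(self) -> dict[str, str]:
        tr = {"B": "log", "T90": "log", "omega2": "log"}
        if self.is_poisson:
            tr["P"] = "logit"
            for nm in self.all_names:
                if nm.startswith("D") and nm[1:].isdigit():
                    tr[nm] = "log"
            tr["slope"] = "log"
            tr["emax"] = "log"
            tr["ed50"] = "log"
        else:
            tr["sigma"] = "log"
            tr["ed50"] = "log"
        return {k: v for k, v in tr.items() if k in self.all_names}

    # -- packing -----------------------------------------------------------
    def pack(self, values: dict[str, float]) -> np.ndarray:
        return np.array([_to_unconstrained(values[n], self.transforms.get(n, "identity"))
                         for n in self.free_names])

    def unpack(self, z: np.ndarray) -> dict[str, float]:
        vals = dict(self.fixed)
        for n, zj in zip(self.free_names, z):
            vals[n] = _from_unconstrained(float(zj), self.transforms.get(n, "identity"))
        return vals

    def parameter_set(self, values: dict[str, float]) -> ParameterSet:
        return ParameterSet(values=dict(values),
                            transforms=dict(self.transforms))

    # -- structural pieces -------------------------------------------------
    def _effect_terms(self, values):
        """Return (n, m) onset*(P_i + D_i) and admissibility margin."""
        d = self.data
        sp = _structural_params(values, self.spec)
        f = onset_fraction(np.where(d.mask, d.t, 0.0), values["T90"])
        from .structural import dose_effect
        d_eff = dose_effect(d.dose, sp.dose_params, self.spec.dose_model)
        p_i = values["P"] + (d.X @ np.array(
            [values[f"beta_{c}"] for c in self.covariates])
            if self.covariates else 0.0)
        return (np.asarray(p_i) + np.asarray(d_eff)).reshape(-1, 1) * f

    def ofv(self, z: np.ndarray) -> float:
        try:
            values = self.unpack(np.asarray(z, float))
        except OverflowError:
            return _PENALTY
        return self.ofv_values(values)

    def ofv_values(self, values: dict[str, float]) -> float:
        d = self.data
        omega2 = values["omega2"]
        eff = self._effect_terms(values)
        if self.is_poisson:
            mult = 1.0 - eff
            margin = np.min(np.where(d.mask, mult, 1.0))
            if margin <= 1e-9 or not np.isfinite(margin):
                return _PENALTY * (1.0 + max(0.0, -margin))
            c = d.ddays * values["B"] * mult
            C = np.sum(np.where(d.mask, c, 0.0), axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                T = np.sum(np.where(d.mask & (d.y > 0), d.y * np.log(c), 0.0), axis=1)
            if omega2 < _OMEGA_TINY:
                return float(-2.0 * np.sum(T - C - self._G))
            eta = _poisson_eta_hat(self._S1, C, omega2, eta0=self._eta_warm)
            self._eta_warm = eta
            H = C * np.exp(eta) + 1.0 / omega2
            logm = (T + eta * self._S1 - C * np.exp(eta) - self._G
                    - eta ** 2 / (2.0 * omega2) - 0.5 * math.log(omega2)
                    - 0.5 * np.log(H))
            return float(-2.0 * np.sum(logm))
        return self._gaussian_ofv(values, eff)

    # -- gaussian ----------------------------------------------------------
    def _gaussian_ofv(self, values, eff) -> float:
        d = self.data
        omega2, sigma, B = values["omega2"], values["sigma"], values["B"]
        if sigma <= 0:
            return _PENALTY
        g = eff  # additive effect in mL (proportional gaussian not used)
        if self.spec.effect_scale == "proportional":
            return _PENALTY  # not a supported combination
        r = np.where(d.mask, d.y - g, 0.0)
        Sr = r.sum(axis=1)
        Sr2 = (r * r).sum(axis=1)
        n = self._nobs
        s2 = sigma * sigma
        if self.eta_model == "linear":
            # exact: eta | y is Gaussian; Laplace coincides with the integral
            r2 = Sr - n * B
            if omega2 < _OMEGA_TINY:
                nll = (n * math.log(2 * math.pi * s2)
                       + (Sr2 - 2 * B * Sr + n * B * B) / s2)
                return float(np.sum(nll))
            eta = r2 / (n + s2 / omega2)
            self._eta_warm = eta
            H = n / s2 + 1.0 / omega2
            quad = Sr2 - 2 * (B + eta) * Sr + n * (B + eta) ** 2
            logm = (-0.5 * n * math.log(2 * math.pi * s2) - quad / (2 * s2)
                    - eta ** 2 / (2 * omega2) - 0.5 * math.log(omega2)
                    - 0.5 * np.log(H))
            return float(-2.0 * np.sum(logm))
        # eta_model == "log": subject mean B e^eta + g, Laplace with damped Newton
        if omega2 < _OMEGA_TINY:
            quad = Sr2 - 2 * B * Sr + n * B * B
            return float(np.sum(n * math.log(2 * math.pi * s2) + quad / s2))
        eta = (self._eta_warm if self._eta_warm is not None
               else np.log(np.clip(Sr / np.maximum(n, 1.0) / B, 0.05, 20.0)))
        eta = np.array(eta, float)

        def grad_hess(eta):
            a = B * np.exp(eta)
            gd = a * (Sr - n * a) / s2 - eta / omega2
            hs = a * (Sr - 2 * n * a) / s2 - 1.0 / omega2
            return gd, hs

        def objective(eta):
            a = B * np.exp(eta)
            return (-(Sr2 - 2 * a * Sr + n * a * a) / (2 * s2)
                    - eta ** 2 / (2 * omega2))

        obj = objective(eta)
        for _ in range(200):
            gd, hs = grad_hess(eta)
            if np.max(np.abs(gd)) < 1e-8:
                break
            step = np.where(hs < 0, -gd / hs, np.sign(gd) * 0.5)
            np.clip(step, -2.0, 2.0, out=step)
            new_eta = eta + step
            new_obj = objective(new_eta)
            # halve steps that decreased the conditional density
            for _ in range(30):
                worse = new_obj < obj - 1e-12
                if not np.any(worse):
                    break
                step = np.where(worse, step * 0.5, step)
                new_eta = eta + step
                new_obj = objective(new_eta)
            eta, obj = new_eta, new_obj
        self._eta_warm = eta
        _, hs = grad_hess(eta)
        if np.any(hs >= 0):
            return _PENALTY
        logm = (-0.5 * n * math.log(2 * math.pi * s2) + obj
                - 0.5 * math.log(omega2) - 0.5 * np.log(-hs))
        return float(-2.0 * np.sum(logm))

    # -- EBEs --------------------------------------------------------------
    def ebe(self, values: dict[str, float]) -> np.ndarray:
        d = self.data
        omega2 = values["omega2"]
        eff = self._effect_terms(values)
        if omega2 < _OMEGA_TINY:
            return np.zeros(d.n_subjects)
        if self.is_poisson:
            mult = 1.0 - eff
            c = d.ddays * values["B"] * mult
            C = np.sum(np.where(d.mask, c, 0.0), axis=1)
            return _poisson_eta_hat(self._S1, C, omega2)
        self._eta_warm = None
        self._gaussian_ofv(values, eff)
        return np.array(self._eta_warm)

    # -- initial values ----------------------------------------------------
    def default_init(self) -> dict[str, float]:
        d = self.data
        at0 = d.mask & (d.t == 0)
        rate = np.where(d.mask, d.y / d.ddays, np.nan)
        b0 = float(np.nansum(np.where(at0, rate, np.nan)) / max(at0.sum(), 1))
        b0 = max(b0, 1e-3)
        last = np.where(d.mask, d.t, -1.0).max(axis=1)
        rate_last = np.array([rate[i, np.argmax(np.where(d.mask[i], d.t[i], -1))]
                              for i in range(d.n_subjects)])
        rate_base = np.array([rate[i, 0] for i in range(d.n_subjects)])
        vals: dict[str, float] = {"B": b0, "T90": 30.0}
        placebo = d.dose == 0
        if self.is_poisson:
            drop = 1.0 - (rate_last[placebo].mean() + 0.25) / (rate_base[placebo].mean() + 0.25)
            vals["P"] = float(np.clip(drop, 0.02, 0.6))
            vals["omega2"] = float(np.clip(
                np.var(np.log(rate_base + 0.5) - math.log(b0 + 0.5)), 0.02, 1.0))
            for nm in self.all_names:
                if nm.startswith("D") and nm[1:].isdigit():
                    vals[nm] = 0.02
            vals["slope"] = 0.005
            vals["emax"], vals["ed50"] = 0.1, 8.0
        else:
            ch = rate_last - rate_base
            vals["P"] = float(ch[placebo].mean()) if placebo.any() else 1.0
            on8 = d.dose == 8
            vals["slope"] = float(max((ch[on8].mean() - vals["P"]) / 8.0, 0.1)) if on8.any() else 1.0
            for nm in self.all_names:
                if nm.startswith("D") and nm[1:].isdigit():
                    vals[nm] = max(vals["slope"] * int(nm[1:]), 0.5)
            vals["emax"], vals["ed50"] = 30.0, 8.0
            vals["sigma"] = float(np.clip(np.std(ch) / math.sqrt(2.0), 1.0, None))
            vals["omega2"] = float(np.clip(
                np.var(np.log(np.clip(rate_base, 1.0, None))) , 0.005, 1.0))
        for c in self.covariates:
            vals[f"beta_{c}"] = 0.0
        _ = last
        return {k: v for k, v in vals.items() if k in self.all_names}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def subject_nll(params: ParameterSet, subject: pd.DataFrame,
                spec: StructuralSpec) -> float:
    """-2 log marginal likelihood contribution of one subject's endpoint rows."""
    values = params.values
    t = subject["TIME_D"].to_numpy(float)
    y = subject["DV"].to_numpy(float)
    dose = float(subject["DOSE_MG"].iloc[0])
    sp = _structural_params(values, spec)
    from .structural import dose_effect
    f = onset_fraction(t, values["T90"])
    eff = (values["P"] + dose_effect(dose, sp.dose_params, spec.dose_model)) * f
    if spec.endpoint_family == "poisson_count":
        dd = pd.to_numeric(subject["DIARY_D"], errors="coerce").to_numpy(float)
        c = dd * values["B"] * (1.0 - eff)
        if np.any(c <= 0):
            return float("inf")
        return poisson_subject_nll_laplace(y, c, values["omega2"])
    # gaussian, additive, log-normal baseline
    data = EndpointData(subj=np.array(["s"]), y=y[None, :], t=t[None, :],
                        ddays=np.ones((1, len(y))),
                        mask=np.ones((1, len(y)), bool),
                        dose=np.array([dose]), X=np.zeros((1, 0)))
    model = _MixedModel(data, spec)
    return model.ofv_values(values)


def posthoc_ebe(params: ParameterSet, data: PooledDataset,
                spec: StructuralSpec, endpoint: str) -> pd.Series:
    """Empirical-Bayes eta estimates (conditional modes) for every subject."""
    ed = build_endpoint_data(data, endpoint)
    model = _MixedModel(ed, spec)
    return pd.Series(model.ebe(params.values), index=pd.Index(ed.subj, name="SUBJ"))


def fit(data: PooledDataset, spec: StructuralSpec,
        init: ParameterSet | None = None, *, endpoint: str,
        covariates: tuple[str, ...] = (),
        fixed: dict[str, float] | None = None,
        eta_model: str = "log",
        compute_cv: bool = True) -> FitResult:
    """Maximize the Laplace marginal likelihood for one endpoint model.

    Deterministic given (data, init).  ``fixed`` pins named parameters at
    given values (excluded from optimization and standard errors).
    CV% is 100 * SE / |estimate| on the natural scale (delta method from the
    inverse observed information on the transformed scale).
    """
    ed = build_endpoint_data(data, endpoint, covariates)
    if ed.n_subjects < 2:
        raise FitError("need at least 2 subjects")
    model = _MixedModel(ed, spec, covariates, fixed, eta_model)
    init_values = model.default_init()
    if init is not None:
        init_values.update({k: v for k, v in init.values.items()
                            if k in model.all_names})
    z0 = model.pack(init_values)
    ofv0 = model.ofv(z0)

    res = minimize(model.ofv, z0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
    best_z, best_ofv, ok = res.x, float(res.fun), bool(res.success)
    if not ok or best_ofv > ofv0 + 1e-6:
        res2 = minimize(model.ofv, best_z if best_ofv <= ofv0 else z0,
                        method="Nelder-Mead",
                        options={"maxiter": 4000, "fatol": 1e-6, "xatol": 1e-6})
        if float(res2.fun) <= best_ofv:
            best_z, best_ofv, ok = res2.x, float(res2.fun), bool(res2.success)
    converged = ok and np.isfinite(best_ofv) and best_ofv < _PENALTY / 2

    values = model.unpack(best_z)
    cov = cv = None
    if compute_cv and converged:
        cov, cv = _covariance_and_cv(model, best_z, values)
    ebe = pd.Series(model.ebe(values), index=pd.Index(ed.subj, name="SUBJ"))
    return FitResult(
        estimates=model.parameter_set(values), ofv=best_ofv,
        cv_percent=cv, ebe=ebe, converged=converged,
        n_subjects=ed.n_subjects, n_obs=ed.n_obs, spec=spec,
        endpoint=endpoint, free_names=list(model.free_names),
        fixed=dict(model.fixed), covariates=tuple(covariates),
        cov_unconstrained=cov, eta_model=eta_model,
        message=str(getattr(res, "message", "")))


def _covariance_and_cv(model: _MixedModel, z: np.ndarray, values):
    """Numerical Hessian of the OFV -> covariance 2*H^-1 -> natural-scale CV%."""
    p = len(z)
    h = 1e-4 * np.maximum(1.0, np.abs(z))
    H = np.zeros((p, p))
    f0 = model.ofv(z)
    for i in range(p):
        for j in range(i, p):
            zi, zj = np.zeros(p), np.zeros(p)
            zi[i], zj[j] = h[i], h[j]
            fpp = model.ofv(z + zi + zj)
            fpm = model.ofv(z + zi - zj)
            fmp = model.ofv(z - zi + zj)
            fmm = model.ofv(z - zi - zj)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    _ = f0
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, None
    dg = np.diag(cov)
    if np.any(dg <= 0) or not np.all(np.isfinite(cov)):
        return None, None
    cv = {}
    for k, name in enumerate(model.free_names):
        theta = values[name]
        se_nat = abs(_dnatural_dz(theta, model.transforms.get(name, "identity"))) * math.sqrt(dg[k])
        cv[name] = 100.0 * se_nat / abs(theta) if theta != 0 else float("inf")
    return cov, cv


def fit_result_to_dict(fr: FitResult) -> dict:
    """JSON-serializable view of a fit (estimates, CV%, OFV, EBEs, covariance)."""
    return {
        "endpoint": fr.endpoint,
        "spec": {"effect_scale": fr.spec.effect_scale,
                 "dose_model": fr.spec.dose_model,
                 "onset": fr.spec.onset,
                 "endpoint_family": fr.spec.endpoint_family},
        "estimates": fr.estimates.values,
        "transforms": fr.estimates.transforms,
        "cv_percent": fr.cv_percent,
        "ofv": fr.ofv,
        "converged": fr.converged,
        "n_subjects": fr.n_subjects,
        "n_obs": fr.n_obs,
        "free_names": fr.free_names,
        "fixed": fr.fixed,
        "covariates": list(fr.covariates),
        "eta_model": fr.eta_model,
        "cov_unconstrained": (None if fr.cov_unconstrained is None
                              else fr.cov_unconstrained.tolist()),
        "ebe": {str(k): float(v) for k, v in fr.ebe.items()},
        "message": fr.message,
    }


def fit_result_from_dict(d: dict) -> FitResult:
    cov = d.get("cov_unconstrained")
    ebe = pd.Series(d.get("ebe", {}), dtype=float)
    ebe.index.name = "SUBJ"
    return FitResult(
        estimates=ParameterSet(values=dict(d["estimates"]),
                               transforms=dict(d.get("transforms", {}))),
        ofv=float(d["ofv"]), cv_percent=d.get("cv_percent"),
        ebe=ebe, converged=bool(d["converged"]),
        n_subjects=int(d["n_subjects"]), n_obs=int(d["n_obs"]),
        spec=StructuralSpec(**d["spec"]), endpoint=d["endpoint"],
        free_names=list(d["free_names"]), fixed=dict(d.get("fixed", {})),
        covariates=tuple(d.get("covariates", ())),
        cov_unconstrained=None if cov is None else np.asarray(cov, float),
        eta_model=d.get("eta_model", "log"), message=d.get("message", ""))


def lrt(fit_reduced: FitResult, fit_full: FitResult) -> float:
    """Likelihood-ratio p-value between nested fits on the same data.

    p = P(chi2_df > max(0, OFV_reduced - OFV_full)) with df the difference
    in the number of free parameters.
    """
    red = set(fit_reduced.free_names) | set(fit_reduced.fixed)
    full = set(fit_full.free_names) | set(fit_full.fixed)
    if not red <= full:
        raise ValueError("models are not nested")
    if (fit_reduced.endpoint != fit_full.endpoint
            or fit_reduced.n_obs != fit_full.n_obs
            or fit_reduced.n_subjects != fit_full.n_subjects):
        raise ValueError("fits are not on the same data")
    df = len(fit_full.free_names) - len(fit_reduced.free_names)
    if df < 1:
        raise ValueError("full model must have more free parameters")
    delta = max(0.0, fit_reduced.ofv - fit_full.ofv)
    return float(chi2.sf(delta, df))
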