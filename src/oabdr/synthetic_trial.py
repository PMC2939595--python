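"""Virtual pooled-trial generator.

Emulates a pooled phase II/III overactive-bladder programme: four
double-blind fixed-dose trials (two 8-week phase II, two 12-week phase III)
randomizing 2514 subjects to placebo or 4/8/12 mg, with 3-day bladder
diaries at each visit.

Statistical structure (the same structure the estimation layer assumes):

* diary counts (micturitions, UUI episodes) are Poisson with subject rate
  ``diary_days * B * exp(eta) * (1 - f(t) * (P + D_dose))``, where
  ``eta ~ N(0, omega^2)`` is log-normal between-subject baseline
  heterogeneity and ``f(t) = 1 - exp(-ln(10) t / T90)`` the onset;
* mean voided volume is Gaussian: ``B * exp(eta) + (P + D_dose) f(t)`` plus
  residual noise;
* PVR > 100 mL ("ever exceeded during treatment") is one Bernoulli per
  subject from a logistic model on baseline PVR, dose, sex, age > 70 and
  the dose x sex / dose x age interactions.

True typical-patient effects are calibrated so that day-84 changes match
the programme's headline values (micturitions -1.2/-1.7/-2.2, UUI
-1.05/-1.26/-1.43, MVV +9.7/+14.2/+28.4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .structural import onset_fraction, solve_emax
from .trial_data import CSV_COLUMNS, PooledDataset

DEFAULT_DIARY_DAYS = 3


class GenerationError(RuntimeError):
    """Inadmissible truth parameters produced a non-positive rate."""


@dataclass
class StudyDesign:
    arms: dict[int, int]              # dose_mg -> n randomized
    schedule: tuple[float, ...]       # visit days, starts at 0
    diary_days: int = DEFAULT_DIARY_DAYS

    def __post_init__(self):
        if any(n < 0 for n in self.arms.values()):
            raise ValueError("arm sizes must be >= 0")
        sched = tuple(float(t) for t in self.schedule)
        if sched != tuple(sorted(sched)) or (sched and sched[0] != 0.0):
            raise ValueError("schedule must be sorted and start at day 0")
        if self.diary_days < 1:
            raise ValueError("diary_days must be >= 1")
        self.schedule = sched

    @property
    def duration_days(self) -> float:
        return self.schedule[-1]


@dataclass
class CovariateSpec:
    """Demographics of the simulated population (trial-typical OAB cohort:
    about 80 % female, mean age 65)."""

    age_mean: float = 65.0
    age_sd: float = 10.0
    frac_female: float = 0.80
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    # baseline PVR in mL: 100 * Beta(a, b), support [0, 100) per the trials'
    # exclusion criterion; mean 20 mL ("PVR in general was low at baseline")
    base_pvr_beta_a: float = 1.2
    base_pvr_beta_b: float = 4.8


@dataclass
class DesignSpec:
    studies: dict[str, StudyDesign]
    covariates: CovariateSpec = field(default_factory=CovariateSpec)

    @property
    def n_subjects(self) -> int:
        return sum(sum(s.arms.values()) for s in self.studies.values())


@dataclass
class PvrLogit:
    """Coefficients of the PVR > 100 mL logistic truth (logit scale)."""

    intercept: float
    basepvr: float      # per mL of baseline PVR
    dose: float         # per mg, women aged <= 70
    male: float
    age70: float        # indicator age > 70
    dose_male: float    # extra per-mg slope in men
    dose_age70: float   # extra per-mg slope above age 70

    def linear_predictor(self, base_pvr, dose_mg, male, age70):
        base_pvr = np.asarray(base_pvr, dtype=float)
        dose_mg = np.asarray(dose_mg, dtype=float)
        male = np.asarray(male, dtype=float)
        age70 = np.asarray(age70, dtype=float)
        return (self.intercept + self.basepvr * base_pvr + self.dose * dose_mg
                + self.male * male + self.age70 * age70
                + self.dose_male * dose_mg * male
                + self.dose_age70 * dose_mg * age70)


@dataclass
class TruthParameters:
    """Generating ("true") parameters for one endpoint."""

    endpoint: str
    baseline_typical: float = 0.0     # B: per 24 h (counts) or mL (MVV)
    bsv_omega2: float = 0.0           # variance of eta (log scale)
    placebo_effect: float = 0.0       # P: fraction (counts) or mL (MVV)
    dose_effects: dict[int, float] = field(default_factory=dict)
    onset_t90_days: float = 27.0
    residual_sd: float | None = None  # mL, MVV only
    pvr_logit: PvrLogit | None = None

    def __post_init__(self):
        if self.onset_t90_days <= 0:
            raise ValueError("T90 must be > 0")
        if self.bsv_omega2 < 0:
            raise ValueError("omega2 must be >= 0")
        if self.endpoint in ("MICT", "UUI") and self.dose_effects:
            if self.placebo_effect + max(self.dose_effects.values()) >= 1:
                raise ValueError("P + max(D) must stay below 1 for count endpoints")


def default_design() -> DesignSpec:
    """The pooled four-study design: 768/759/762/225 subjects on
    placebo/4 mg/8 mg/12 mg (total 2514); 12 mg arms exist only in phase II."""
    return DesignSpec(studies={
        "P2A": StudyDesign({0: 183, 4: 186, 8: 172, 12: 186}, (0, 14, 28, 56)),
        "P2B": StudyDesign({0: 43, 4: 44, 8: 47, 12: 39}, (0, 14, 28, 56)),
        "P3A": StudyDesign({0: 277, 4: 263, 8: 276, 12: 0}, (0, 14, 28, 56, 84)),
        "P3B": StudyDesign({0: 265, 4: 266, 8: 267, 12: 0}, (0, 14, 28, 56, 84)),
    })


# PVR truth coefficients.  Baseline PVR dominates, dose effects concentrate
# in men and subjects over 70.  The intercept is frozen from
# calibrate_pvr_intercept() on the default design so the marginal exceedance
# rate is 6.8 % (161/2385).
_PVR_TRUTH_UNCALIBRATED = dict(
    basepvr=0.045, dose=0.02, male=0.7, age70=0.3,
    dose_male=0.10, dose_age70=0.06,
)
_PVR_INTERCEPT_DEFAULT = -4.4179  # calibrate_pvr_intercept(default_design(), ...)


def default_truth(endpoint: str) -> TruthParameters:
    """Truth calibration reproducing the headline day-84 typical changes.

    * MICT: B = 11/24 h, placebo fraction 1.2/11, drug fractions linear in
      dose (0.5/11 per 4 mg step beyond placebo), T90 = 27 d.
    * UUI: B = 2/24 h, T90 = 120 d (still rising at day 84; the onset has
      not plateaued), asymptotic fractions rescaled by 1/f(84) so the
      *day-84* changes are -1.05/-1.26/-1.43; the 12 mg effect comes from
      the Emax curve through the 4 and 8 mg points.
    * MVV: additive, B = 156 mL, placebo +9.7 mL, drug +14.2/+28.4/+42.6 mL
      (linear), T90 = 18 d, residual SD 35 mL.
    * PVR: logistic exceedance truth (see :class:`PvrLogit`).
    """
    if endpoint == "MICT":
        return TruthParameters(
            endpoint="MICT", baseline_typical=11.0, bsv_omega2=0.09,
            placebo_effect=1.2 / 11.0,
            dose_effects={4: 0.5 / 11.0, 8: 1.0 / 11.0, 12: 1.5 / 11.0},
            onset_t90_days=27.0,
        )
    if endpoint == "UUI":
        t90 = 120.0
        scale = 1.0 / onset_fraction(84.0, t90)   # day-84 -> asymptote
        e4, e8 = 0.21 / 2.0, 0.38 / 2.0
        emax, ed50 = solve_emax(4.0, e4, 8.0, e8)
        e12 = emax * 12.0 / (ed50 + 12.0)
        return TruthParameters(
            endpoint="UUI", baseline_typical=2.0, bsv_omega2=0.36,
            placebo_effect=(1.05 / 2.0) * scale,
            dose_effects={4: e4 * scale, 8: e8 * scale, 12: e12 * scale},
            onset_t90_days=t90,
        )
    if endpoint == "MVV":
        return TruthParameters(
            endpoint="MVV", baseline_typical=156.0, bsv_omega2=0.04,
            placebo_effect=9.7,
            dose_effects={4: 14.2, 8: 28.4, 12: 42.6},
            onset_t90_days=18.0, residual_sd=35.0,
        )
    if endpoint == "PVR":
        return TruthParameters(
            endpoint="PVR",
            pvr_logit=PvrLogit(intercept=_PVR_INTERCEPT_DEFAULT,
                               **_PVR_TRUTH_UNCALIBRATED),
        )
    raise ValueError(f"unknown endpoint {endpoint!r}")


def default_truth_map() -> dict[str, TruthParameters]:
    return {e: default_truth(e) for e in ("MICT", "UUI", "MVV", "PVR")}


# ---------------------------------------------------------------------------
# subject frame and per-endpoint simulation
# ---------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(int(seed))
    names = ("subjects", "MICT", "UUI", "MVV", "PVR")
    return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


def _subject_frame(design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for study_id, study in design.studies.items():
        i = 0
        for dose in sorted(study.arms):
            for _ in range(study.arms[dose]):
                i += 1
                rows.append((f"{study_id}-{i:04d}", study_id, dose))
    subj = pd.DataFrame(rows, columns=["SUBJ", "STUDY", "DOSE_MG"])
    n = len(subj)
    cov = design.covariates
    subj["AGE"] = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 18.0, 95.0).round(1)
    subj["SEX"] = np.where(rng.random(n) < cov.frac_female, "F", "M")
    subj["BMI"] = np.clip(rng.normal(cov.bmi_mean, cov.bmi_sd, n), 15.0, 45.0).round(1)
    subj["BASE_PVR"] = (
        100.0 * rng.beta(cov.base_pvr_beta_a, cov.base_pvr_beta_b, n)
    ).round(1).clip(0.0, 99.9)
    return subj


def _effect_multiplier(truth: TruthParameters, dose: np.ndarray,
                       sched: np.ndarray) -> np.ndarray:
    """(n, m) array of 1 - f(t) (P + D_d) with admissibility check."""
    f = onset_fraction(sched, truth.onset_t90_days)
    d_map = {0: 0.0, **truth.dose_effects}
    try:
        d_eff = np.array([d_map[int(d)] for d in dose], dtype=float)
    except KeyError as err:
        raise GenerationError(f"no truth effect for dose {err.args[0]} mg") from None
    return 1.0 - (truth.placebo_effect + d_eff)[:, None] * f[None, :]


def _simulate_count_endpoint(truth, subj, design, rng):
    """Per-study vectorized Poisson draws; returns long rows + eta."""
    frames = []
    eta_all = pd.Series(index=subj["SUBJ"], dtype=float)
    for study_id, study in design.studies.items():
        grp = subj[subj["STUDY"] == study_id]
        if len(grp) == 0:
            continue
        sched = np.asarray(study.schedule, dtype=float)
        dose = grp["DOSE_MG"].to_numpy()
        eta = rng.normal(0.0, math.sqrt(truth.bsv_omega2), len(grp))
        mult = _effect_multiplier(truth, dose, sched)
        if np.any(mult <= 0):
            i, _ = np.argwhere(mult <= 0)[0]
            raise GenerationError(
                f"rate <= 0 for subject {grp['SUBJ'].iloc[i]!r}: "
                "effect fraction P + D >= 1"
            )
        lam = (study.diary_days * truth.baseline_typical
               * np.exp(eta)[:, None] * mult)
        y = rng.poisson(lam)
        n, m = y.shape
        frames.append(pd.DataFrame({
            "SUBJ": np.repeat(grp["SUBJ"].to_numpy(), m),
            "TIME_D": np.tile(sched, n),
            "ENDPOINT": truth.endpoint,
            "DV": y.ravel().astype(float),
            "DIARY_D": study.diary_days,
        }))
        eta_all.loc[grp["SUBJ"]] = eta
    if not frames:
        return pd.DataFrame(columns=["SUBJ", "TIME_D", "ENDPOINT", "DV", "DIARY_D"]), eta_all
    return pd.concat(frames, ignore_index=True), eta_all


def _simulate_mvv(truth, subj, design, rng):
    frames = []
    for study_id, study in design.studies.items():
        grp = subj[subj["STUDY"] == study_id]
        if len(grp) == 0:
            continue
        sched = np.asarray(study.schedule, dtype=float)
        dose = grp["DOSE_MG"].to_numpy()
        eta = rng.normal(0.0, math.sqrt(truth.bsv_omega2), len(grp))
        f = onset_fraction(sched, truth.onset_t90_days)
        d_map = {0: 0.0, **truth.dose_effects}
        d_eff = np.array([d_map[int(d)] for d in dose], dtype=float)
        mean = (truth.baseline_typical * np.exp(eta)[:, None]
                + (truth.placebo_effect + d_eff)[:, None] * f[None, :])
        y = mean + rng.normal(0.0, truth.residual_sd, mean.shape)
        y = np.clip(y, 1.0, None)   # voided volumes are physically positive
        n, m = y.shape
        frames.append(pd.DataFrame({
            "SUBJ": np.repeat(grp["SUBJ"].to_numpy(), m),
            "TIME_D": np.tile(sched, n),
            "ENDPOINT": "MVV",
            "DV": np.round(y.ravel(), 1),
            "DIARY_D": pd.NA,
        }))
    if not frames:
        return pd.DataFrame(columns=["SUBJ", "TIME_D", "ENDPOINT", "DV", "DIARY_D"])
    return pd.concat(frames, ignore_index=True)


def _pvr_exceed(subj: pd.DataFrame, logit: PvrLogit,
                rng: np.random.Generator) -> np.ndarray:
    male = (subj["SEX"] == "M").to_numpy(dtype=float)
    age70 = (subj["AGE"] > 70).to_numpy(dtype=float)
    lp = logit.linear_predictor(subj["BASE_PVR"].to_numpy(),
                                subj["DOSE_MG"].to_numpy(), male, age70)
    return rng.random(len(subj)) < expit(lp)


def simulate_pvr(design: DesignSpec, truth: TruthParameters,
                 seed: int) -> pd.DataFrame:
    """One-row-per-subject PVR > 100 mL exceedance table."""
    streams = _streams(seed)
    subj = _subject_frame(design, streams["subjects"])
    cols = ["SUBJ", "STUDY", "DOSE_MG", "SEX", "AGE", "BASE_PVR", "EXCEED100"]
    if len(subj) == 0:
        return pd.DataFrame(columns=cols)
    subj = subj.copy()
    subj["EXCEED100"] = _pvr_exceed(subj, truth.pvr_logit, streams["PVR"])
    return subj[cols]


def simulate_trial(design: DesignSpec, truth: dict[str, TruthParameters],
                   seed: int, validate: bool = True) -> PooledDataset:
    """Simulate the pooled programme for the endpoints present in ``truth``.

    Deterministic: the same (design, truth, seed) gives byte-identical data.
    Baseline covariate columns (BASE_MICT/...) hold the observed day-0
    per-24 h values when the endpoint is simulated, else the typical value.
    """
    streams = _streams(seed)
    subj = _subject_frame(design, streams["subjects"])
    obs_frames = []
    base_cols = {"BASE_MICT": 11.0, "BASE_UUI": 2.0, "BASE_MVV": 156.0}

    for ep in ("MICT", "UUI"):
        if ep in truth:
            rows, _ = _simulate_count_endpoint(truth[ep], subj, design, streams[ep])
            obs_frames.append(rows)
            day0 = rows[rows["TIME_D"] == 0].set_index("SUBJ")
            base_cols[f"BASE_{ep}"] = (
                day0["DV"] / day0["DIARY_D"].astype(float)
            ).reindex(subj["SUBJ"]).to_numpy()
    if "MVV" in truth:
        rows = _simulate_mvv(truth["MVV"], subj, design, streams["MVV"])
        obs_frames.append(rows)
        day0 = rows[rows["TIME_D"] == 0].set_index("SUBJ")
        base_cols["BASE_MVV"] = day0["DV"].reindex(subj["SUBJ"]).to_numpy()
    if "PVR" in truth and len(subj):
        exceed = _pvr_exceed(subj, truth["PVR"].pvr_logit, streams["PVR"])
        # one end-of-study PVR measurement consistent with the exceedance flag
        rng = streams["PVR"]
        low = np.minimum(subj["BASE_PVR"].to_numpy() + rng.exponential(15.0, len(subj)), 99.0)
        high = 100.0 + rng.exponential(50.0, len(subj))
        value = np.round(np.where(exceed, high, low), 1)
        last = subj["STUDY"].map(
            {sid: s.duration_days for sid, s in design.studies.items()}
        ).to_numpy(dtype=float)
        obs_frames.append(pd.DataFrame({
            "SUBJ": subj["SUBJ"].to_numpy(), "TIME_D": last,
            "ENDPOINT": "PVR", "DV": value, "DIARY_D": pd.NA,
        }))

    subj = subj.assign(**base_cols)
    if obs_frames:
        obs = pd.concat(obs_frames, ignore_index=True)
    else:
        obs = pd.DataFrame(columns=["SUBJ", "TIME_D", "ENDPOINT", "DV", "DIARY_D"])
    df = obs.merge(subj, on="SUBJ", how="left")
    ep_order = pd.CategoricalDtype(["MICT", "UUI", "MVV", "PVR"], ordered=True)
    df["_ep"] = df["ENDPOINT"].astype(ep_order)
    subj_order = pd.CategoricalDtype(subj["SUBJ"].tolist(), ordered=True)
    df["_subj"] = df["SUBJ"].astype(subj_order)
    df = (df.sort_values(["_subj", "_ep", "TIME_D"], kind="stable")
            .drop(columns=["_ep", "_subj"]).reset_index(drop=True))
    df["DIARY_D"] = pd.array(df["DIARY_D"], dtype="Int64")
    df = df.reindex(columns=CSV_COLUMNS)
    ds = PooledDataset(df=df, provenance=f"synthetic: seed={seed}")
    return ds.validate() if validate else ds


def calibrate_pvr_intercept(design: DesignSpec, logit: PvrLogit,
                            target: float = 0.068,
                            n_subjects: int = 200_000,
                            seed: int = 20_260_924) -> float:
    """Root-find the intercept giving marginal P(exceed) = ``target``.

    Uses a large Monte-Carlo draw of covariates from the design's
    distributions (doses weighted by pooled arm sizes); deterministic for a
    fixed seed.  Used once to freeze the default truth intercept.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    cov = design.covariates
    doses, weights = [], []
    for s in design.studies.values():
        for d, n in s.arms.items():
            doses.append(d)
            weights.append(n)
    w = np.array(weights, dtype=float)
    dose = rng.choice(doses, size=n_subjects, p=w / w.sum())
    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n_subjects), 18, 95)
    male = (rng.random(n_subjects) >= cov.frac_female).astype(float)
    base_pvr = 100.0 * rng.beta(cov.base_pvr_beta_a, cov.base_pvr_beta_b, n_subjects)
    lp0 = replace(logit, intercept=0.0).linear_predictor(
        base_pvr, dose, male, (age > 70).astype(float))
    return float(brentq(lambda b0: expit(b0 + lp0).mean() - target, -15.0, 5.0))
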