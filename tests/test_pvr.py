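"""PVR > 100 mL logistic exceedance model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import binom

from oabdr.pvr import (
    DEFAULT_COVARIATES, LogisticFit, LogisticSpec, SeparationError,
    compare_dose_models, exceedance_summary, fit_logistic,
    predict_probability, subgroup_rates,
)
from oabdr.synthetic_trial import default_design, default_truth, simulate_pvr


def paper_counts_table() -> pd.DataFrame:
    """Deterministic exceedance table with 161 events among 2385 subjects
    (synthetic stand-in for the pooled safety population)."""
    n = 2385
    rng = np.random.default_rng(2385)
    tab = pd.DataFrame({
        "SUBJ": [f"S{i:04d}" for i in range(n)],
        "DOSE_MG": rng.choice([0, 4, 8, 12], size=n),
        "SEX": rng.choice(["F", "M"], size=n, p=[0.8, 0.2]),
        "AGE": rng.uniform(40, 85, size=n).round(1),
        "BASE_PVR": rng.uniform(0, 99, size=n).round(1),
    })
    tab["EXCEED100"] = np.arange(n) < 161
    return tab


@pytest.fixture(scope="module")
def exceed_2385():
    return paper_counts_table()


@pytest.fixture(scope="module")
def simulated_exceed():
    return simulate_pvr(default_design(), default_truth("PVR"), 17)


def irls_logistic(X: np.ndarray, y: np.ndarray, n_iter=60) -> np.ndarray:
    """Textbook iteratively-reweighted least squares (test oracle)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        delta = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - p))
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-12:
            break
    return beta


class TestFitLogistic:
    def test_intercept_only_closed_form(self, exceed_2385):
        fr = fit_logistic(exceed_2385,
                          LogisticSpec(covariates=(), include_dose=False))
        assert fr.events == 161 and fr.n == 2385
        assert fr.coefficients["intercept"] == pytest.approx(
            math.log(161 / 2224), abs=1e-6)

    def test_matches_irls_oracle_on_fuzzed_data(self):
        rng = np.random.default_rng(7)
        for rep in range(5):
            n = 400
            tab = pd.DataFrame({
                "SUBJ": [f"S{i}" for i in range(n)],
                "DOSE_MG": rng.choice([0, 4, 8, 12], size=n),
                "SEX": rng.choice(["F", "M"], size=n),
                "AGE": rng.uniform(40, 85, size=n),
                "BASE_PVR": rng.uniform(0, 99, size=n),
            })
            lp = -2.5 + 0.02 * tab["BASE_PVR"] + 0.05 * tab["DOSE_MG"]
            tab["EXCEED100"] = rng.random(n) < expit(lp)
            spec = LogisticSpec(covariates=("baseline_pvr", "sex", "age70"))
            fr = fit_logistic(tab, spec)
            X = np.column_stack([
                np.ones(n), tab["DOSE_MG"].to_numpy(float),
                tab["BASE_PVR"].to_numpy(float),
                (tab["SEX"] == "M").to_numpy(float),
                (tab["AGE"] > 70).to_numpy(float)])
            oracle = irls_logistic(X, tab["EXCEED100"].to_numpy(float))
            assert np.max(np.abs(fr.coefficients.to_numpy() - oracle)) < 1e-6

    def test_null_covariate_coefficient_near_zero(self, simulated_exceed):
        tab = simulated_exceed.copy()
        rng = np.random.default_rng(0)
        tab["BMI"] = rng.uniform(20, 35, len(tab))
        fr = fit_logistic(tab, LogisticSpec(covariates=("baseline_pvr", "bmi")))
        assert abs(fr.zvalues()["bmi"]) < 3.0

    def test_baseline_pvr_dominates_on_synthetic_truth(self, simulated_exceed):
        fr = fit_logistic(simulated_exceed,
                          LogisticSpec(covariates=("baseline_pvr", "sex", "age70")))
        z = fr.zvalues().drop(["intercept"]).abs()
        assert z.idxmax() == "baseline_pvr"

    def test_separation_error_names_covariate(self):
        tab = pd.DataFrame({
            "SUBJ": [f"S{i}" for i in range(40)],
            "DOSE_MG": [0, 8] * 20,
            "SEX": ["F"] * 40,
            "AGE": [60.0] * 40,
            "BASE_PVR": np.r_[np.full(20, 10.0), np.full(20, 90.0)],
            "EXCEED100": np.r_[np.zeros(20, bool), np.ones(20, bool)],
        })
        with pytest.raises(SeparationError, match="baseline_pvr"):
            fit_logistic(tab, LogisticSpec(covariates=("baseline_pvr",)))

    def test_all_events_rejected(self, exceed_2385):
        tab = exceed_2385.copy()
        tab["EXCEED100"] = True
        with pytest.raises(SeparationError):
            fit_logistic(tab, LogisticSpec(covariates=()))

    def test_interactions_require_main_effects(self):
        with pytest.raises(ValueError, match="main effect"):
            LogisticSpec(covariates=("dose_x_sex",))

    def test_aic_definition(self, exceed_2385):
        fr = fit_logistic(exceed_2385, LogisticSpec(covariates=("baseline_pvr",)))
        k = 3  # intercept + dose + baseline_pvr
        assert fr.aic == pytest.approx(2 * k - 2 * fr.llf, rel=1e-12)


class TestPredict:
    def test_all_zero_coefficients_give_half(self):
        fr = LogisticFit(
            coefficients=pd.Series({"intercept": 0.0, "dose": 0.0}),
            bse=pd.Series({"intercept": 1.0, "dose": 1.0}),
            llf=0.0, aic=0.0, n=0, events=0,
            spec=LogisticSpec(covariates=()), columns=["intercept", "dose"])
        assert predict_probability({}, 8, fr) == pytest.approx(0.5)

    def test_inverse_of_intercept_only(self, exceed_2385):
        fr = fit_logistic(exceed_2385,
                          LogisticSpec(covariates=(), include_dose=False))
        p = predict_probability({}, 0, fr)
        assert p == pytest.approx(161 / 2385, abs=1e-6)
        assert p == pytest.approx(expit(math.log(161 / 2224)), abs=1e-9)

    def test_monotone_in_dose(self, simulated_exceed):
        fr = fit_logistic(simulated_exceed)
        covs = {"baseline_pvr": 30.0, "sex": 1.0, "age70": 1.0}
        probs = [predict_probability(covs, d, fr) for d in (0, 4, 8, 12)]
        assert probs == sorted(probs)

    def test_unknown_covariate_rejected(self, simulated_exceed):
        fr = fit_logistic(simulated_exceed)
        with pytest.raises(ValueError, match="unknown"):
            predict_probability({"weight": 80}, 4, fr)


class TestDoseModelComparison:
    def test_single_dose_level_is_reparameterization(self, exceed_2385):
        tab = exceed_2385[exceed_2385["DOSE_MG"].isin([0, 4])].copy()
        out = compare_dose_models(tab, covariates=("baseline_pvr",))
        assert out["delta_aic_linear_minus_sqrt"] == pytest.approx(0.0, abs=1e-5)
        assert out["selected"] == "linear"

    def test_linear_truth_keeps_linear(self, simulated_exceed):
        out = compare_dose_models(simulated_exceed)
        assert out["selected"] == "linear"
        assert abs(out["delta_aic_linear_minus_sqrt"]) < 6.0

    def test_concave_truth_prefers_sqrt(self):
        rng = np.random.default_rng(11)
        n = 12000
        tab = pd.DataFrame({
            "SUBJ": [f"S{i}" for i in range(n)],
            "DOSE_MG": rng.choice([0, 4, 8, 12], size=n),
            "SEX": rng.choice(["F", "M"], size=n),
            "AGE": rng.uniform(40, 85, size=n),
            "BASE_PVR": rng.uniform(0, 99, size=n),
        })
        lp = -3.0 + 1.0 * np.sqrt(tab["DOSE_MG"].to_numpy(float))
        tab["EXCEED100"] = rng.random(n) < expit(lp)
        out = compare_dose_models(tab, covariates=())
        assert out["selected"] == "sqrt"
        assert out["delta_aic_linear_minus_sqrt"] > 2.0


class TestSubgroups:
    def test_quantile_ordering(self, simulated_exceed):
        fr = fit_logistic(simulated_exceed)
        tab = subgroup_rates(simulated_exceed, fr, n_sims=300, seed=4)
        filled = tab[~tab["empty"]]
        assert (filled["q10"] <= filled["q50"]).all()
        assert (filled["q50"] <= filled["q90"]).all()

    def test_quantiles_match_binomial(self):
        n = 400
        tab = pd.DataFrame({
            "SUBJ": [f"S{i}" for i in range(n)],
            "DOSE_MG": 0, "SEX": "F", "AGE": 60.0, "BASE_PVR": 20.0,
            "EXCEED100": [True] * 40 + [False] * (n - 40),
        })
        p0 = 0.1
        fr = LogisticFit(
            coefficients=pd.Series({"intercept": float(logit(p0))}),
            bse=pd.Series({"intercept": 0.1}), llf=0.0, aic=0.0,
            n=n, events=40, spec=LogisticSpec(covariates=(), include_dose=False),
            columns=["intercept"])
        out = subgroup_rates(tab, fr, n_sims=1000, seed=9)
        cell = out[(out["sex"] == "F") & (~out["age_gt_70"])].iloc[0]
        for q, col in ((0.1, "q10"), (0.5, "q50"), (0.9, "q90")):
            expected = binom.ppf(q, n, p0) / n
            assert cell[col] == pytest.approx(expected, abs=0.012)

    def test_interaction_truth_shows_dose_dependence_in_men(self):
        from conftest import scaled_design

        tab = simulate_pvr(scaled_design(3.0), default_truth("PVR"), 23)
        fr = fit_logistic(tab)
        out = subgroup_rates(tab, fr, n_sims=300, seed=1)
        men = out[(out["sex"] == "M") & (out["age_gt_70"])]
        women = out[(out["sex"] == "F") & (~out["age_gt_70"])]
        men_rise = (men[men["dose_mg"] == 8]["q50"].iloc[0]
                    - men[men["dose_mg"] == 0]["q50"].iloc[0])
        women_rise = (women[women["dose_mg"] == 8]["q50"].iloc[0]
                      - women[women["dose_mg"] == 0]["q50"].iloc[0])
        assert men_rise > women_rise
        assert men_rise > 0.02


class TestThresholds:
    def test_nested_event_sets(self, tiny_design):
        from oabdr.synthetic_trial import default_truth_map, simulate_trial

        ds = simulate_trial(tiny_design, default_truth_map(), 5)
        summary = exceedance_summary(ds.endpoint_frame("PVR"))
        assert summary["exceed_100"] >= summary["exceed_150"] >= summary["exceed_200"]

    def test_paper_count_rates(self, exceed_2385):
        # percentage formatting on the frozen counts
        rates = {100: 161, 150: 57, 200: 11}
        for thr, k in rates.items():
            assert round(100.0 * k / 2385, 1) == {100: 6.8, 150: 2.4, 200: 0.5}[thr]
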