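"""Laplace marginal likelihood, empirical-Bayes estimates and LRT machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, poisson

from oabdr.nlme import (
    FitResult, ParameterSet, _MixedModel, build_endpoint_data, fit,
    fit_result_from_dict, fit_result_to_dict, lrt,
    poisson_subject_nll_agq, poisson_subject_nll_laplace, posthoc_ebe,
    subject_nll,
)
from oabdr.structural import StructuralSpec, onset_fraction
from oabdr.synthetic_trial import default_truth, simulate_trial
from oabdr.trial_data import PooledDataset

from conftest import poisson_subject, scaled_design

PROP_CAT = StructuralSpec(effect_scale="proportional", dose_model="categorical",
                          endpoint_family="poisson_count")
GAUSS_LIN = StructuralSpec(effect_scale="additive", dose_model="linear",
                           endpoint_family="gaussian")

MICT_TRUTH_VALUES = {
    "B": 11.0, "P": 1.2 / 11.0, "D4": 0.5 / 11.0, "D8": 1.0 / 11.0,
    "D12": 1.5 / 11.0, "T90": 27.0, "omega2": 0.09,
}


class TestSubjectLikelihood:
    def test_degenerate_omega_equals_plain_poisson(self):
        y = np.array([30.0, 28.0, 25.0])
        c = np.array([33.0, 30.0, 27.0])
        expected = -2.0 * poisson.logpmf(y, c).sum()
        assert poisson_subject_nll_laplace(y, c, 0.0) == pytest.approx(
            expected, abs=1e-10)

    def test_laplace_matches_quadrature_at_moderate_bsv(self):
        y = np.array([35.0, 30.0, 29.0, 25.0])
        c = np.array([33.0, 33.0, 30.0, 28.0])
        lap = poisson_subject_nll_laplace(y, c, 0.09)
        agq = poisson_subject_nll_agq(y, c, 0.09, n_nodes=64)
        assert lap == pytest.approx(agq, abs=1e-3)

    def test_laplace_matches_quadrature_on_fuzzed_subjects(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            y, c, omega2 = poisson_subject(rng)
            diff = abs(poisson_subject_nll_laplace(y, c, omega2)
                       - poisson_subject_nll_agq(y, c, omega2))
            worst = max(worst, diff)
        assert worst < 1e-2

    def test_subject_nll_wrapper(self, handmade_dataset):
        subj = handmade_dataset.endpoint_frame("MICT")
        subj = subj[subj["SUBJ"] == "P3A-0001"]
        params = ParameterSet(values=MICT_TRUTH_VALUES)
        got = subject_nll(params, subj, PROP_CAT)
        # same quantity assembled by hand
        f = onset_fraction(subj["TIME_D"].to_numpy(float), 27.0)
        c = 3.0 * 11.0 * (1.0 - f * (1.2 / 11.0))
        expected = poisson_subject_nll_laplace(
            subj["DV"].to_numpy(float), c, 0.09)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_gaussian_linear_matches_closed_form(self, tiny_design):
        ds = simulate_trial(tiny_design, {"MVV": default_truth("MVV")}, 9)
        ed = build_endpoint_data(ds, "MVV")
        model = _MixedModel(ed, GAUSS_LIN, eta_model="linear")
        values = {"B": 150.0, "P": 8.0, "slope": 3.0, "T90": 20.0,
                  "omega2": 120.0, "sigma": 30.0}
        got = model.ofv_values(values)
        # closed form: y_i ~ N(B + g_i, sigma^2 I + omega2 J)
        expected = 0.0
        for i in range(ed.n_subjects):
            m = ed.mask[i]
            f = onset_fraction(ed.t[i, m], values["T90"])
            g = values["B"] + (values["P"] + values["slope"] * ed.dose[i]) * f
            cov = (values["sigma"] ** 2 * np.eye(m.sum())
                   + values["omega2"] * np.ones((m.sum(), m.sum())))
            expected += -2.0 * multivariate_normal.logpdf(
                ed.y[i, m], mean=g, cov=cov)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_gaussian_lognormal_laplace_close_to_linear_at_small_bsv(self, tiny_design):
        # with omega2 -> small the log-normal and additive baselines agree
        ds = simulate_trial(tiny_design, {"MVV": default_truth("MVV")}, 9)
        ed = build_endpoint_data(ds, "MVV")
        log_model = _MixedModel(ed, GAUSS_LIN, eta_model="log")
        values = {"B": 156.0, "P": 9.7, "slope": 3.55, "T90": 18.0,
                  "omega2": 1e-12, "sigma": 35.0}
        lin_values = dict(values)
        got = log_model.ofv_values(values)
        lin_model = _MixedModel(ed, GAUSS_LIN, eta_model="linear")
        assert got == pytest.approx(lin_model.ofv_values(lin_values), rel=1e-9)


class TestEmpiricalBayes:
    def test_prior_dominates_as_omega_vanishes(self, mict_small):
        params = ParameterSet(values={**MICT_TRUTH_VALUES, "omega2": 1e-14})
        ebe = posthoc_ebe(params, mict_small, PROP_CAT, "MICT")
        assert np.allclose(ebe.to_numpy(), 0.0)

    def test_high_counts_give_positive_eta(self, handmade_dataset):
        df = handmade_dataset.df.copy()
        df.loc[df["ENDPOINT"] == "MICT", "DV"] = [70.0, 68.0, 75.0, 71.0]
        ds = PooledDataset(df=df)
        params = ParameterSet(values=MICT_TRUTH_VALUES)
        ebe = posthoc_ebe(params, ds, PROP_CAT, "MICT")
        assert (ebe > 0).all()

    def test_gaussian_linear_ebe_is_posterior_mean(self, tiny_design):
        ds = simulate_trial(tiny_design, {"MVV": default_truth("MVV")}, 9)
        ed = build_endpoint_data(ds, "MVV")
        model = _MixedModel(ed, GAUSS_LIN, eta_model="linear")
        values = {"B": 150.0, "P": 8.0, "slope": 3.0, "T90": 20.0,
                  "omega2": 120.0, "sigma": 30.0}
        ebe = model.ebe(values)
        for i in range(ed.n_subjects):
            m = ed.mask[i]
            f = onset_fraction(ed.t[i, m], values["T90"])
            g = values["B"] + (values["P"] + values["slope"] * ed.dose[i]) * f
            resid = (ed.y[i, m] - g).sum()
            n = m.sum()
            post_mean = resid / (n + values["sigma"] ** 2 / values["omega2"])
            assert ebe[i] == pytest.approx(post_mean, abs=1e-8)


class TestFit:
    def test_descent_from_truth_init(self, mict_small):
        ed = build_endpoint_data(mict_small, "MICT")
        model = _MixedModel(ed, PROP_CAT)
        init_ofv = model.ofv_values(MICT_TRUTH_VALUES)
        fr = fit(mict_small, PROP_CAT,
                 ParameterSet(values=MICT_TRUTH_VALUES), endpoint="MICT",
                 compute_cv=False)
        assert fr.converged
        assert fr.ofv <= init_ofv + 1e-6

    def test_likelihood_additivity_under_duplication(self, mict_small):
        ed = build_endpoint_data(mict_small, "MICT")
        model = _MixedModel(ed, PROP_CAT)
        single = model.ofv_values(MICT_TRUTH_VALUES)
        df = mict_small.df
        dup = pd.concat([df, df.assign(SUBJ="dup-" + df["SUBJ"])],
                        ignore_index=True)
        ds2 = PooledDataset(df=dup)
        model2 = _MixedModel(build_endpoint_data(ds2, "MICT"), PROP_CAT)
        assert model2.ofv_values(MICT_TRUTH_VALUES) == pytest.approx(
            2.0 * single, rel=1e-12)

    def test_duplication_leaves_estimates_unchanged(self, mict_small):
        fr1 = fit(mict_small, PROP_CAT, endpoint="MICT", compute_cv=False)
        df = mict_small.df
        dup = PooledDataset(df=pd.concat(
            [df, df.assign(SUBJ="dup-" + df["SUBJ"])], ignore_index=True))
        fr2 = fit(dup, PROP_CAT, fr1.estimates, endpoint="MICT",
                  compute_cv=False)
        assert fr2.ofv == pytest.approx(2.0 * fr1.ofv, rel=1e-4)
        for name in ("B", "P", "D8"):
            assert fr2.estimates.values[name] == pytest.approx(
                fr1.estimates.values[name], rel=0.05)

    def test_small_sample_recovery(self, mict_small):
        fr = fit(mict_small, PROP_CAT, endpoint="MICT", compute_cv=False)
        assert fr.converged
        assert float(fr.typical_change(11.0, 8, 84.0)) == pytest.approx(
            -2.2, abs=0.45)

    def test_placebo_effect_estimator_unbiased(self):
        # ~n=400 subjects per replicate; bias must be small relative to the
        # replicate spread
        design = scaled_design(0.16)
        estimates = []
        for seed in range(20):
            ds = simulate_trial(design, {"MICT": default_truth("MICT")},
                                100 + seed)
            fr = fit(ds, PROP_CAT, endpoint="MICT", compute_cv=False)
            estimates.append(fr.estimates.values["P"])
        estimates = np.array(estimates)
        bias = estimates.mean() - 1.2 / 11.0
        se_mean = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(bias) < 0.5 * estimates.std(ddof=1)
        assert abs(bias) < 4 * se_mean  # sanity on the Monte-Carlo check

    def test_serialization_round_trip(self, mict_small):
        fr = fit(mict_small, PROP_CAT, endpoint="MICT")
        back = fit_result_from_dict(fit_result_to_dict(fr))
        assert back.ofv == fr.ofv
        assert back.estimates.values == fr.estimates.values
        assert back.spec == fr.spec
        assert float(back.typical_change(11.0, 8, 84.0)) == pytest.approx(
            float(fr.typical_change(11.0, 8, 84.0)))


def _dummy_fit(ofv, free_names, endpoint="MICT", n_obs=100):
    return FitResult(
        estimates=ParameterSet(values={n: 1.0 for n in free_names}),
        ofv=ofv, cv_percent=None, ebe=pd.Series(dtype=float), converged=True,
        n_subjects=10, n_obs=n_obs, spec=PROP_CAT, endpoint=endpoint,
        free_names=list(free_names), fixed={}, covariates=(),
        cov_unconstrained=None)


class TestLRT:
    def test_zero_delta_gives_p_one(self):
        red = _dummy_fit(100.0, ["B", "P"])
        full = _dummy_fit(100.0, ["B", "P", "D8"])
        assert lrt(red, full) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta, p", [(6.635, 0.01), (10.828, 0.001)])
    def test_chi_square_thresholds(self, delta, p):
        red = _dummy_fit(100.0 + delta, ["B", "P"])
        full = _dummy_fit(100.0, ["B", "P", "D8"])
        assert lrt(red, full) == pytest.approx(p, abs=5e-5)

    def test_non_nested_rejected(self):
        red = _dummy_fit(100.0, ["B", "P", "slope"])
        full = _dummy_fit(99.0, ["B", "P", "D8"])
        with pytest.raises(ValueError, match="nested"):
            lrt(red, full)

    def test_different_data_rejected(self):
        red = _dummy_fit(100.0, ["B", "P"], n_obs=100)
        full = _dummy_fit(99.0, ["B", "P", "D8"], n_obs=120)
        with pytest.raises(ValueError, match="same data"):
            lrt(red, full)
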