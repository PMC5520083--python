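"""Estimator checks against brute-force likelihood oracles and reference libraries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from survgwas import (
    FitResult,
    Scenario,
    SingularInformationError,
    calibrate_params,
    cox_fit,
    logistic_fit,
    prentice_cox_fit,
    simulate_cohort,
    wald_test,
)
from survgwas.cohort import CohortColumns as C


def make_frame(time, event, x, in_subcohort=None):
    df = pd.DataFrame(
        {
            C.OBSERVED_TIME: np.asarray(time, float),
            C.IS_CASE: np.asarray(event, bool),
            "x": np.asarray(x, float),
        }
    )
    if in_subcohort is not None:
        df[C.IN_SUBCOHORT] = np.asarray(in_subcohort, bool)
        df[C.IN_ANALYSIS] = df[C.IS_CASE] | df[C.IN_SUBCOHORT]
    return df


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        # 4 subjects, all events at distinct times: the partial likelihood is a
        # product over shrinking risk sets, maximised here on a 1-D grid.
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_logpl(beta):
            ll = 0.0
            for i in range(4):
                risk = np.exp(beta * x[i:])
                ll += beta * x[i] - math.log(risk.sum())
            return -ll

        oracle = optimize.minimize_scalar(neg_logpl, bounds=(-10, 10), method="bounded",
                                          options={"xatol": 1e-12})
        fit = cox_fit(make_frame([1, 2, 3, 4], [1, 1, 1, 1], x), covariates=("x",))
        assert fit.converged
        assert fit.estimates["x"] == pytest.approx(oracle.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-9)

    def test_mirrored_groups_give_zero(self):
        # Appending a copy with the exposure flipped makes the likelihood
        # symmetric in beta, so the maximiser is exactly zero.
        t = [1.0, 2.0, 3.0, 4.0]
        x = [1.0, 0.0, 0.0, 1.0]
        frame = make_frame(t + t, [1] * 8, x + [1 - v for v in x])
        fit = cox_fit(frame, covariates=("x",))
        assert fit.estimates["x"] == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_lifelines(self, small_cohort):
        from lifelines import CoxPHFitter

        df = small_cohort.head(200)
        fit = cox_fit(df)
        cph = CoxPHFitter()
        cph.fit(
            df[[C.OBSERVED_TIME, C.IS_CASE, C.GENOTYPE, C.AGE]],
            duration_col=C.OBSERVED_TIME,
            event_col=C.IS_CASE,
        )
        assert np.allclose(fit.estimates.to_numpy(), cph.params_.to_numpy(), atol=1e-6)
        assert np.allclose(fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_efron_equals_breslow_without_ties(self, small_cohort):
        fe = cox_fit(small_cohort, ties="efron")
        fb = cox_fit(small_cohort, ties="breslow")
        assert np.allclose(fe.estimates.to_numpy(), fb.estimates.to_numpy(), atol=1e-10)

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(17)
        t = rng.integers(1, 6, size=80).astype(float)  # heavy ties
        x = rng.normal(size=80)
        d = rng.random(80) < 0.7
        frame = make_frame(t, d, x)
        fit = cox_fit(frame, covariates=("x",))
        cph = CoxPHFitter()
        cph.fit(frame[[C.OBSERVED_TIME, C.IS_CASE, "x"]], C.OBSERVED_TIME, C.IS_CASE)
        assert fit.estimates["x"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se["x"] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_monotone_likelihood_flagged_not_raised(self):
        # Exposure perfectly ordered with failure time: beta runs away and the
        # fit must report non-convergence rather than raise.
        fit = cox_fit(
            make_frame([1, 2, 3, 4, 5, 6], [1] * 6, [5, 4, 3, 2, 1, 0]), covariates=("x",)
        )
        assert not fit.converged

    def test_collinear_covariates_raise_named_error(self, small_cohort):
        df = small_cohort.assign(genotype_copy=small_cohort[C.GENOTYPE])
        with pytest.raises((SingularInformationError, ValueError)):
            cox_fit(df, covariates=(C.GENOTYPE, "genotype_copy"))

    def test_no_cases_rejected(self, small_cohort):
        df = small_cohort.assign(is_case=False)
        with pytest.raises(ValueError, match="at least one case"):
            cox_fit(df)

    def test_shift_and_scale_invariance(self, small_cohort):
        base = cox_fit(small_cohort)
        shifted = small_cohort.assign(age=small_cohort[C.AGE] + 100.0)
        assert cox_fit(shifted).estimates[C.AGE] == pytest.approx(
            base.estimates[C.AGE], abs=1e-8
        )
        scaled = small_cohort.assign(age=small_cohort[C.AGE] * 4.0)
        fs = cox_fit(scaled)
        assert fs.estimates[C.AGE] == pytest.approx(base.estimates[C.AGE] / 4.0, abs=1e-8)
        assert fs.se[C.AGE] == pytest.approx(base.se[C.AGE] / 4.0, abs=1e-8)

    def test_unbiased_at_scale(self):
        # Gold-standard property: mean genotype log(HR) over replicates sits on
        # the true value for the full-cohort Cox model.
        scenario = Scenario(
            design="cohort", n_cohort=25_000, raf=0.10, hr=1.5, incidence=0.15,
            censoring="complete", n_replicates=500, seed=99,
        )
        params = calibrate_params(scenario)
        seeds = np.random.SeedSequence(scenario.seed).spawn(500)
        betas = np.empty(500)
        for i, s in enumerate(seeds):
            df = simulate_cohort(scenario, params, np.random.default_rng(s))
            betas[i] = cox_fit(df).estimates[C.GENOTYPE]
        mc_se = betas.std(ddof=1) / math.sqrt(len(betas))
        assert abs(betas.mean() - math.log(1.5)) < 3 * mc_se


class TestPrenticeCoxFit:
    def test_whole_cohort_subcohort_degenerates_to_cox(self, small_cohort):
        full = cox_fit(small_cohort, robust=True)
        pren = prentice_cox_fit(small_cohort)  # in_subcohort all True
        assert np.allclose(pren.estimates.to_numpy(), full.estimates.to_numpy(), atol=1e-10)
        assert np.allclose(pren.se.to_numpy(), full.se.to_numpy(), atol=1e-10)

    def test_matches_enumerated_pseudo_likelihood(self):
        # Toy case-cohort: subcohort {A,B,C,D}, external cases {E,F}. The
        # pseudo-likelihood is written out risk set by risk set and maximised
        # on a 1-D bracket; external cases appear only in their own risk set.
        t = [2.0, 3.0, 4.0, 5.0, 1.5, 3.5]
        d = [1, 0, 1, 0, 1, 1]
        x = [1.0, 0.0, 0.0, 1.0, 1.0, 0.0]
        insc = [1, 1, 1, 1, 0, 0]
        frame = make_frame(t, d, x, in_subcohort=insc)

        def neg_logpl(beta):
            e = np.exp(beta * np.asarray(x))
            ll = 0.0
            ll += beta * x[4] - math.log(e[4] + e[0] + e[1] + e[2] + e[3])  # E @ 1.5
            ll += beta * x[0] - math.log(e[0] + e[1] + e[2] + e[3])  # A @ 2.0
            ll += beta * x[5] - math.log(e[5] + e[2] + e[3])  # F @ 3.5
            ll += beta * x[2] - math.log(e[2] + e[3])  # C @ 4.0
            return -ll

        oracle = optimize.minimize_scalar(neg_logpl, bounds=(-10, 10), method="bounded",
                                          options={"xatol": 1e-12})
        fit = prentice_cox_fit(frame, covariates=("x",))
        assert fit.converged
        assert fit.estimates["x"] == pytest.approx(oracle.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-9)

    def test_robust_se_near_jackknife(self, small_case_cohort):
        analysis = small_case_cohort[small_case_cohort[C.IN_ANALYSIS]].reset_index(drop=True)
        fit = prentice_cox_fit(analysis)
        beta_hat = fit.estimates[C.GENOTYPE]
        deltas = []
        for i in range(len(analysis)):
            sub = analysis.drop(index=i)
            deltas.append(beta_hat - prentice_cox_fit(sub).estimates[C.GENOTYPE])
        jackknife_se = math.sqrt(np.sum(np.square(deltas)))
        assert fit.se[C.GENOTYPE] == pytest.approx(jackknife_se, rel=0.10)

    def test_requires_subcohort_flags(self, small_cohort):
        df = small_cohort.drop(columns=[C.IN_SUBCOHORT])
        with pytest.raises(ValueError, match="in_subcohort"):
            prentice_cox_fit(df)


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        # a=10 exposed cases, b=90 exposed controls, c=5, d=95: the MLE is the
        # sample log odds ratio with Woolf standard error.
        y = [1] * 10 + [0] * 90 + [1] * 5 + [0] * 95
        x = [1.0] * 100 + [0.0] * 100
        frame = pd.DataFrame({C.IS_CASE: np.asarray(y, bool), "x": x,
                              C.OBSERVED_TIME: 1.0})
        fit = logistic_fit(frame, covariates=("x",))
        assert fit.estimates["x"] == pytest.approx(math.log(10 * 95 / (90 * 5)), abs=1e-8)
        assert fit.se["x"] == pytest.approx(
            math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95), abs=1e-8
        )

    def test_equal_case_fraction_gives_zero(self):
        rows = []
        for g in (0, 1, 2):
            rows += [(g, True)] * 5 + [(g, False)] * 45
        frame = pd.DataFrame(rows, columns=[C.GENOTYPE, C.IS_CASE])
        frame[C.OBSERVED_TIME] = 1.0
        fit = logistic_fit(frame, covariates=(C.GENOTYPE,))
        assert fit.estimates[C.GENOTYPE] == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_statsmodels(self, small_cohort):
        import statsmodels.api as sm

        fit = logistic_fit(small_cohort)
        X = sm.add_constant(small_cohort[[C.GENOTYPE, C.AGE]].to_numpy())
        ref = sm.Logit(small_cohort[C.IS_CASE].to_numpy(float), X).fit(disp=0)
        assert np.allclose(fit.estimates.to_numpy(), ref.params, atol=1e-8)
        assert np.allclose(fit.se.to_numpy(), ref.bse, atol=1e-8)

    def test_case_cohort_fitting_set_is_cases_plus_subcohort(self, small_case_cohort):
        fit = logistic_fit(small_case_cohort)
        expected_n = int(small_case_cohort[C.IN_ANALYSIS].sum())
        assert fit.n_obs == expected_n
        assert fit.n_events == int(small_case_cohort[C.IS_CASE].sum())

    def test_separation_flagged_not_raised(self):
        frame = pd.DataFrame(
            {C.IS_CASE: [True] * 5 + [False] * 5, "x": [1.0] * 5 + [0.0] * 5,
             C.OBSERVED_TIME: 1.0}
        )
        fit = logistic_fit(frame, covariates=("x",))
        assert not fit.converged

    def test_degenerate_outcome_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="cases and non-cases"):
            logistic_fit(small_cohort.assign(is_case=True))

    def test_loglik_no_worse_than_intercept_only(self, small_cohort):
        fit = logistic_fit(small_cohort)
        ybar = small_cohort[C.IS_CASE].mean()
        null_ll = len(small_cohort) * (
            ybar * math.log(ybar) + (1 - ybar) * math.log(1 - ybar)
        )
        assert fit.loglik >= null_ll


class TestWaldTest:
    @staticmethod
    def _fit(beta, se):
        idx = pd.Index(["x"])
        return FitResult(
            model="cox",
            estimates=pd.Series([beta], index=idx),
            se=pd.Series([se], index=idx),
        )

    def test_zero_estimate_gives_p_one(self):
        assert wald_test(self._fit(0.0, 1.0), "x") == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "z,p", [(1.959964, 0.05), (3.890592, 1e-4)]
    )
    def test_normal_quantiles(self, z, p):
        assert wald_test(self._fit(z, 1.0), "x") == pytest.approx(p, rel=1e-4)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            wald_test(self._fit(1.0, 0.0), "x")

    def test_unconverged_rejected(self):
        fit = self._fit(1.0, 1.0)
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            wald_test(fit, "x")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    shift=st.floats(-50, 50),
    scale=st.floats(0.1, 10),
    seed=st.integers(0, 2**16),
)
def test_logistic_affine_equivariance(shift, scale, seed):
    """Shifting a covariate leaves its slope unchanged; scaling by c divides slope and SE by c."""
    rng = np.random.default_rng(seed)
    n = 120
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
    y = rng.random(n) < p
    if y.all() or not y.any():
        return
    frame = pd.DataFrame({C.IS_CASE: y, "x": x, C.OBSERVED_TIME: 1.0})
    base = logistic_fit(frame, covariates=("x",))
    if not base.converged:
        return
    moved = logistic_fit(frame.assign(x=x * scale + shift), covariates=("x",))
    assert moved.estimates["x"] == pytest.approx(base.estimates["x"] / scale, rel=1e-6)
    assert moved.se["x"] == pytest.approx(base.se["x"] / scale, rel=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    u=st.floats(1e-6, 1 - 1e-6),
    lam=st.floats(1e-5, 1e-2),
    v=st.floats(0.3, 4.0),
    beta=st.floats(-1.0, 1.0),
)
def test_event_time_inverts_survival(u, lam, v, beta):
    """S(T(u)) = u: the generated time sits exactly at survival probability u."""
    from survgwas import WeibullParams, event_time

    p = WeibullParams(lam, v, 0.0, beta)
    t = event_time(u, 0.0, 1, p)
    rate = lam * math.exp(beta)
    assert math.exp(-rate * t**v) == pytest.approx(u, rel=1e-9)
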