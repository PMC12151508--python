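import numpy as np
import pytest

from jmspm.cohort import Cohort, CohortConfig, Individual, default_params, generate_cohort
from jmspm.spm import (
    HYPOTHESES, MomentState, SPMData, SPMParams, allostatic_load,
    eval_components, fit_spm, gompertz_cum_hazard, mean_hazard,
    propagate_moments, run_hypothesis_suite, spm_loglik,
)


def make_params(**kw):
    base = dict(
        aY=-0.5, bY=0.0, betaY=0.0, sigma1=0.4, betaW=0.0,
        af0=1.0, bf0=0.0, betaf0=0.0, af1=1.0, bf1=0.0, betaf1=0.0,
        aQ=0.0, bQ=0.0, betaQ=0.0,
        ln_amu0=np.log(1e-3), bmu0=0.09, betamu0=np.zeros(1), sigma0=0.3,
    )
    base.update(kw)
    return SPMParams(**base)


class TestComponents:
    def test_age_constant_feedback(self):
        p = make_params(aY=-0.3)
        for t, c in [(55, 0), (90, 1)]:
            a, *_ = eval_components(p, t, c)
            assert a == pytest.approx(-0.3)

    def test_linear_equilibrium_arithmetic(self):
        p = make_params(af1=2.0, bf1=-0.01, betaf1=-0.3)
        a, b, f0, f1, Q, mu0 = eval_components(p, 60.0, 1.0)
        assert f1 == pytest.approx(2.0 - 0.01 * 10 - 0.3)

    def test_gompertz_at_tmin(self):
        p = make_params(ln_amu0=np.log(0.001), bmu0=0.09)
        *_, mu0 = eval_components(p, 50.0, 0.0)
        assert mu0 == pytest.approx(0.001)

    def test_parameter_sign_constraints(self):
        with pytest.raises(ValueError):
            make_params(aY=0.1)
        with pytest.raises(ValueError):
            make_params(sigma1=-1.0)
        with pytest.raises(ValueError):
            make_params(sigma0=0.0)


class TestMeanHazard:
    def test_minimum_at_optimum(self):
        p = make_params(aQ=0.02)
        mu = mean_hazard(MomentState(m=1.0, gamma=0.0, t=70.0), p, 0.0)
        _, _, _, _, _, mu0 = eval_components(p, 70.0, 0.0)
        assert mu == pytest.approx(mu0)
        # U-shape: moving m away from f0 in either direction raises the hazard
        for dm in (-0.5, 0.5):
            assert mean_hazard(MomentState(1.0 + dm, 0.0, 70.0), p, 0.0) > mu

    def test_variance_contribution(self):
        p = make_params(aQ=0.02)
        mu = mean_hazard(MomentState(m=1.0, gamma=0.5, t=70.0), p, 0.0)
        _, _, _, _, _, mu0 = eval_components(p, 70.0, 0.0)
        assert mu == pytest.approx(mu0 + 0.02 * 0.5)

    def test_q_zero_reduces_to_baseline(self):
        p = make_params(aQ=0.0)
        mu = mean_hazard(MomentState(m=42.0, gamma=9.0, t=70.0), p, 0.0)
        _, _, _, _, _, mu0 = eval_components(p, 70.0, 0.0)
        assert mu == pytest.approx(mu0, rel=1e-6)


class TestAllostaticLoad:
    def test_zero_when_trajectories_coincide(self):
        p = make_params()
        for t, c in [(50, 0), (75, 1), (100, 0)]:
            assert allostatic_load(p, t, c) == 0.0

    def test_linear_gap_arithmetic(self):
        p = make_params(af0=1.0, af1=1.0, bf0=0.01, bf1=-0.005)
        assert allostatic_load(p, 60.0, 0.0) == pytest.approx(0.15)

    def test_gap_grows_with_age_beyond_crossing(self):
        p = make_params(af0=1.0, af1=1.0, bf0=0.01, bf1=-0.005)
        ages = np.linspace(50, 100, 11)
        al = [allostatic_load(p, t, 0.0) for t in ages]
        assert np.all(np.diff(al) > 0)


class TestPropagation:
    def test_zero_length_interval_is_identity(self):
        p = make_params()
        st = MomentState(m=0.7, gamma=0.2, t=65.0)
        out, ch = propagate_moments(st, p, 0.0, 65.0)
        assert (out.m, out.gamma) == (0.7, 0.2)
        assert ch == 0.0

    def test_ou_limits(self):
        p = make_params(sigma1=0.4, ln_amu0=np.log(1e-8))
        st = MomentState(m=2.0, gamma=0.0, t=50.0)
        out, _ = propagate_moments(st, p, 0.0, 110.0, step=0.01)
        assert out.gamma == pytest.approx(0.4**2 / (2 * 0.5), rel=1e-3)
        assert out.m == pytest.approx(1.0, abs=1e-6)
        # transient: m decays toward f1 exponentially at rate |a|
        mid, _ = propagate_moments(st, p, 0.0, 52.0, step=0.001)
        assert mid.m == pytest.approx(1.0 + 1.0 * np.exp(-0.5 * 2.0), rel=1e-3)

    def test_cum_hazard_matches_gompertz_closed_form(self):
        p = make_params(aQ=0.0)
        st = MomentState(m=1.0, gamma=0.0, t=60.0)
        _, ch = propagate_moments(st, p, 0.0, 80.0, step=0.002)
        assert ch == pytest.approx(gompertz_cum_hazard(p, 60.0, 80.0, 0.0),
                                   rel=2e-3)


def _one_subject_cohort(y, t0=70.0, T=70.0, death=0, sex=0, covs=None):
    ind = Individual("s0", "f0", sex, covs if covs is not None else {},
                     t0, [t0], [y], T, death)
    return Cohort([ind])


class TestLoglik:
    def test_single_censored_observation_closed_form(self):
        p = default_params()
        y = 0.42
        c = _one_subject_cohort(y, covs={"smoker": 0.0})
        _, _, _, f1, _, _ = eval_components(p, 70.0, 0.0)
        expected = -0.5 * np.log(2 * np.pi * p.sigma0**2) \
            - 0.5 * (y - f1)**2 / p.sigma0**2
        assert spm_loglik(c, p) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_subject_order_and_family_labels(self, small_cohort,
                                                          spm_true_params):
        base = spm_loglik(small_cohort, spm_true_params)
        inds = list(small_cohort.individuals)[::-1]
        relabeled = [Individual(
            i.subject_id, "XX" + i.family_id, i.sex, i.covariates, i.t0,
            i.visit_ages, i.y_values, i.event_age, i.death) for i in inds]
        assert spm_loglik(Cohort(relabeled), spm_true_params) == \
            pytest.approx(base, rel=1e-12)

    def test_grid_step_consistency(self, small_cohort, spm_true_params):
        l1 = spm_loglik(small_cohort, spm_true_params, step=0.1)
        l2 = spm_loglik(small_cohort, spm_true_params, step=0.05)
        assert abs(l1 - l2) / abs(l2) < 1e-3

    def test_gompertz_survival_factor_closed_form(self):
        # Q = 0: the survival part of a death subject's loglik is the
        # Gompertz integral; the trajectory part is the initial density
        p = make_params(aQ=0.0, sigma1=0.3, sigma0=0.25)
        y, t0, T = 0.9, 65.0, 74.0
        c = _one_subject_cohort(y, t0=t0, T=T, death=1)
        ll = spm_loglik(c, p, step=0.002)
        dens = -0.5 * np.log(2 * np.pi * 0.25**2) - 0.5 * (y - 1.0)**2 / 0.25**2
        surv = -gompertz_cum_hazard(p, t0, T, 0.0)
        lnmu = np.log(np.exp(p.ln_amu0 + p.bmu0 * (T - 50.0)))
        assert ll == pytest.approx(dens + surv + lnmu, abs=2e-3)


@pytest.fixture()
def fitted_suite(spm_suite):
    return spm_suite


class TestFitting:
    def test_unrestricted_beats_truth_and_converges(self, fitted_suite,
                                                    spm_true_params,
                                                    small_cohort):
        _, unres, _ = fitted_suite
        assert unres.converged
        assert unres.loglik >= spm_loglik(small_cohort, spm_true_params) - 1e-6

    def test_restriction_mechanism_fixes_values(self, fitted_suite):
        data, unres, _ = fitted_suite
        rfit = fit_spm(data, restrictions={"bQ": 0.0}, start=unres.params)
        assert rfit.params.bQ == 0.0
        assert rfit.loglik <= unres.loglik + 1e-6

    def test_tie_restriction_equalizes_trajectories(self, fitted_suite):
        data, unres, _ = fitted_suite
        rfit = fit_spm(data, restrictions=HYPOTHESES["ALzero"][0],
                       start=unres.params)
        assert rfit.params.af0 == pytest.approx(rfit.params.af1)
        assert rfit.params.bf0 == pytest.approx(rfit.params.bf1)
        assert rfit.params.betaf0 == pytest.approx(rfit.params.betaf1)

    def test_nonbinding_restriction_gives_unit_pvalue(self, fitted_suite):
        from scipy import stats as ss
        data, unres, _ = fitted_suite
        # restricting a parameter to its unrestricted MLE should cost nothing
        rfit = fit_spm(data, restrictions={"betaQ": unres.params.betaQ},
                       start=unres.params)
        stat = max(0.0, 2 * (unres.loglik - rfit.loglik))
        assert ss.chi2.sf(stat, 1) > 0.9

    def test_hypothesis_suite_structure(self, fitted_suite):
        _, _, lrts = fitted_suite
        names = [r.h0_name for r in lrts]
        assert names == list(HYPOTHESES.keys())
        dfs = {r.h0_name: r.df for r in lrts}
        assert dfs["Qzero"] == 3 and dfs["ALzero"] == 3 and dfs["ALnoT"] == 2
        assert all(df == 1 for h, df in dfs.items()
                   if h not in ("Qzero", "ALzero", "ALnoT"))
        for r in lrts:
            assert 0.0 <= r.p_value <= 1.0
            assert r.statistic >= 0.0

    def test_no_event_cohort_rejected(self):
        ind = Individual("s0", "f0", 0, {"smoker": 0.0}, 70.0, [70.0], [0.1],
                         80.0, 0)
        with pytest.raises(ValueError):
            fit_spm(Cohort([ind]))
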