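import numpy as np
import pytest

from jmspm.cohort import CohortConfig, default_params, generate_cohort
from jmspm.jm import (
    JMData, JMFit, JMParams, fit_jm, fit_lme, hr_from_alpha, hr_per_sd,
    jm_loglik, jm_residuals, piecewise_exponential_loglik, simulate_jm_cohort,
)


@pytest.fixture(scope="module")
def jm_cohort(jm_true_params):
    # wider visit-2 window than the cohort emulation: separates the residual
    # variance from the random-slope variance with only two visits
    return simulate_jm_cohort(jm_true_params, 400, seed=13,
                              visit2_offset_sd=2.5, attendance=0.7)


@pytest.fixture(scope="module")
def jm_data(jm_cohort):
    return JMData.from_cohort(jm_cohort)


@pytest.fixture(scope="module")
def stage1(jm_data):
    return fit_lme(jm_data)


class TestHRHelpers:
    def test_hr_is_exp_alpha(self):
        hr, ci = hr_from_alpha(-0.341)
        assert hr == pytest.approx(0.711, abs=5e-4)
        assert ci is None
        assert hr_from_alpha(0.0)[0] == 1.0

    def test_wald_ci_ordered_and_centered(self):
        hr, (lo, hi) = hr_from_alpha(-0.3, se=0.1)
        assert lo < hr < hi
        assert np.sqrt(lo * hi) == pytest.approx(hr, rel=1e-12)

    def test_hr_per_sd(self):
        assert hr_per_sd(-0.436, 0.553) == pytest.approx(0.786, abs=1.5e-3)
        assert hr_per_sd(-5.0, 1e-12) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            hr_per_sd(0.3, -1.0)


class TestTimeOrigin:
    def test_longitudinal_clock_is_time_since_baseline(self, jm_data):
        assert np.allclose(jm_data.tau[:, 0], 0.0)

    def test_survival_clock_is_event_minus_baseline(self, jm_cohort, jm_data):
        expect = [i.event_age - i.t0 for i in jm_cohort.individuals]
        np.testing.assert_allclose(jm_data.s, expect)


class TestLME:
    def test_recovers_known_mixed_model(self, stage1, jm_true_params):
        # informative-dropout bias of the LME-only fit is mild at these rates
        np.testing.assert_allclose(stage1.beta, jm_true_params.beta, atol=0.15)
        assert stage1.sigma2 == pytest.approx(jm_true_params.sigma2, abs=0.06)
        assert stage1.D[0, 0] == pytest.approx(jm_true_params.D[0, 0], abs=0.15)

    def test_single_observation_subjects_retained(self, jm_cohort, stage1,
                                                  jm_data):
        singles = [k for k, i in enumerate(jm_cohort.individuals)
                   if len(i.visit_ages) == 1]
        assert singles
        assert stage1.eb_modes.shape[0] == jm_data.n
        assert np.isfinite(stage1.eb_modes[singles]).all()

    def test_zero_noise_identical_subjects_degenerate(self):
        # every subject lies exactly on the same line y = 1 + 0.5 t,
        # regardless of covariates: D ~ 0 and beta recovers the line
        from jmspm.cohort import Cohort, Individual
        rng = np.random.default_rng(2)
        inds = []
        for k in range(40):
            t0 = float(rng.uniform(60, 80))
            off = float(rng.uniform(3, 9))
            inds.append(Individual(
                f"d{k}", f"df{k}", int(rng.random() < 0.5),
                {"smoker": float(rng.random() < 0.4)}, t0,
                [t0, t0 + off], [1.0, 1.0 + 0.5 * off], t0 + 20.0, k % 2))
        data = JMData.from_cohort(Cohort(inds))
        s1 = fit_lme(data)
        assert s1.beta[0] == pytest.approx(1.0, abs=1e-3)
        assert s1.beta[-1] == pytest.approx(0.5, abs=1e-3)
        np.testing.assert_allclose(s1.beta[1:4], 0.0, atol=1e-3)
        assert np.all(np.abs(s1.eb_modes) < 1e-2)


class TestLoglik:
    def test_alpha_zero_separates(self, jm_data, stage1):
        from jmspm.jm import _pe_start
        log_h0, gamma = _pe_start(jm_data)
        p = JMParams(beta=stage1.beta, sigma2=stage1.sigma2, D=stage1.D,
                     log_h0=log_h0, gamma=gamma, association="none")
        joint = jm_loglik(jm_data, p, n_quad=9, stage1=stage1)
        split = stage1.loglik + piecewise_exponential_loglik(jm_data, log_h0,
                                                             gamma)
        assert joint == pytest.approx(split, abs=1e-6)

    def test_quadrature_converged_at_default_order(self, jm_data, stage1,
                                                   jm_true_params):
        l9 = jm_loglik(jm_data, jm_true_params, n_quad=9, stage1=stage1)
        l15 = jm_loglik(jm_data, jm_true_params, n_quad=15, stage1=stage1)
        assert abs(l9 - l15) < 1e-3

    def test_invariant_to_subject_order(self, jm_cohort, jm_true_params):
        from jmspm.cohort import Cohort
        rev = Cohort(list(jm_cohort.individuals)[::-1])
        d1 = JMData.from_cohort(jm_cohort)
        d2 = JMData.from_cohort(rev)
        s1, s2 = fit_lme(d1), fit_lme(d2)
        assert jm_loglik(d1, jm_true_params, 9, s1) == pytest.approx(
            jm_loglik(d2, jm_true_params, 9, s2), rel=1e-10)

    def test_rejects_too_few_nodes(self, jm_data, jm_true_params):
        with pytest.raises(ValueError):
            jm_loglik(jm_data, jm_true_params, n_quad=2)


class TestNesting:
    def test_association_nesting_on_same_data(self, jm_true_params):
        cohort = simulate_jm_cohort(jm_true_params, 150, seed=4)
        data = JMData.from_cohort(cohort)
        f_int = fit_jm(data, association="int", n_quad=5, compute_se=False)
        f_is = fit_jm(data, association="intslope", n_quad=5, compute_se=False)
        assert f_is.loglik >= f_int.loglik - 1e-4


class TestResiduals:
    def _truth_fit(self, data, p):
        s1 = fit_lme(data)
        return JMFit(association=p.association, params=p, loglik=np.nan,
                     converged=True, n_subjects=data.n, alphas={}, sd_b={},
                     eb_modes=s1.eb_modes, stage1=s1)

    def test_zero_noise_residuals_vanish(self):
        from jmspm.cohort import Cohort, Individual
        rng = np.random.default_rng(3)
        inds = []
        for k in range(30):
            t0 = float(rng.uniform(60, 80))
            inds.append(Individual(
                f"z{k}", f"zf{k}", int(rng.random() < 0.5),
                {"smoker": float(rng.random() < 0.4)}, t0,
                [t0, t0 + float(rng.uniform(3, 9))], [0.8, 0.8],
                t0 + 20.0, k % 2))
        data = JMData.from_cohort(Cohort(inds))
        p = JMParams(beta=np.array([0.8, 0, 0, 0, 0.0]), sigma2=1e-6,
                     D=np.diag([1e-8, 1e-9]),
                     log_h0=np.full(data.n_seg, np.log(0.03)),
                     gamma=np.zeros(3), association="none")
        std, _, _ = jm_residuals(self._truth_fit(data, p), data)
        assert np.all(np.abs(std) < 1e-2)

    def test_marginal_residual_coverage_near_95(self, jm_true_params):
        cohort = simulate_jm_cohort(jm_true_params, 700, seed=8)
        data = JMData.from_cohort(cohort)
        _, _, frac = jm_residuals(self._truth_fit(data, jm_true_params), data)
        assert 0.92 < frac < 0.985

    def test_cox_snell_mean_unit_exponential(self, jm_true_params):
        # near-complete follow-up: cumulative hazards at observed death times
        # behave like unit-exponential draws, so their mean is ~1
        p = jm_true_params
        cohort = simulate_jm_cohort(p, 600, seed=15, admin_censor=120.0,
                                    visit2_offset_sd=2.5, attendance=0.7)
        data = JMData.from_cohort(
            cohort, knots=cohort.provenance["baseline_knots"])
        assert data.delta.mean() > 0.95
        _, cs, _ = jm_residuals(self._truth_fit(data, p), data)
        dead = data.delta == 1
        assert cs[dead].mean() == pytest.approx(1.0, abs=0.15)


class TestDegenerate:
    def test_intslope_zero_slope_variance_flagged(self):
        p = JMParams(
            beta=np.array([0.2, -0.3, -0.25, 0.05, -0.03]), sigma2=0.05,
            D=np.array([[0.4, 0.0], [0.0, 1e-14]]),
            log_h0=np.log(np.full(6, 0.04)),
            gamma=np.array([0.3, 0.6, 0.2]), association="int", alpha0=-0.4)
        cohort = simulate_jm_cohort(p, 250, seed=30)
        fit = fit_jm(JMData.from_cohort(cohort), association="intslope",
                     n_quad=5, compute_se=False, maxiter=60)
        assert any("alpha1" in f or "slope" in f for f in fit.flags)
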