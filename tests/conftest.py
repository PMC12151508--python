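import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from jmspm.cohort import CohortConfig, default_params, generate_cohort
from jmspm.jm import JMParams


@pytest.fixture(scope="session")
def spm_true_params():
    return default_params()


@pytest.fixture(scope="session")
def small_cohort(spm_true_params):
    """~200-subject SPM-generated family cohort shared across tests."""
    cfg = CohortConfig(n_families=32, seed=1)
    return generate_cohort(cfg, spm_true_params)


@pytest.fixture(scope="session")
def spm_suite(small_cohort):
    """Unrestricted SPM fit plus the 12-hypothesis LRT suite, shared by the
    unit and acceptance tests (the 13 fits dominate suite runtime)."""
    from jmspm.spm import SPMData, fit_spm, run_hypothesis_suite
    data = SPMData.from_cohort(small_cohort)
    unres = fit_spm(data, step=0.1)
    lrts = run_hypothesis_suite(data, step=0.1, unrestricted=unres)
    return data, unres, lrts


@pytest.fixture(scope="session")
def jm_true_params():
    """A joint-model truth with a clearly negative current-value association."""
    return JMParams(
        beta=np.array([0.2, -0.3, -0.25, 0.05, -0.03]),
        sigma2=0.10,
        D=np.array([[0.5, -0.02], [-0.02, 0.004]]),
        log_h0=np.log(np.array([0.02, 0.03, 0.04, 0.05, 0.07, 0.09])),
        gamma=np.array([0.3, 0.6, 0.2]),
        association="current_value",
        alpha=-0.3,
    )
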