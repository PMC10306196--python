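import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vasoreact as vr

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_pop():
    """Noise-free population config for exact recovery checks."""
    return vr.PopulationConfig(diameter_noise_mm=0.0, bp_noise_mmhg=0.0)


@pytest.fixture(scope="session")
def table_truth(quiet_pop):
    """A subject fixed at the population-mean parameters."""
    return vr.SubjectTruth(
        subject="S000", d_bas=4.01, sbp=125.0, dbp=76.0, hr=60.0,
        fmd_pct=6.41, fms_pct=-7.25, pwv_bas=8.58,
        strain_bas=vr.invert_baseline_strain(8.58, 125.0, 76.0),
        peak_time_s=60.0, gamma_shape=2.5, seed=1,
    )


@pytest.fixture(scope="session")
def mean_trace(table_truth, quiet_pop):
    trace, bp = vr.simulate_trace(table_truth, quiet_pop)
    return trace, bp


@pytest.fixture(scope="session")
def small_study():
    return vr.simulate_study(n_subjects=12, seed=7)
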