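import numpy as np
import pytest

from tcisim import (
    PatientDemographics,
    PumpConfig,
    Urgency,
    mean_cohort_demographics,
    schnider_parameters,
)


@pytest.fixture(scope="session")
def mean_patient() -> PatientDemographics:
    return mean_cohort_demographics(incision_to_delivery=6.1)


@pytest.fixture(scope="session")
def params_tpeak(mean_patient):
    return schnider_parameters(mean_patient)


@pytest.fixture(scope="session")
def params_fixed(mean_patient):
    return schnider_parameters(mean_patient, ke0_mode="fixed")


@pytest.fixture(scope="session")
def pump_cfg() -> PumpConfig:
    return PumpConfig()


def euler_trace(params, rate_fn, duration_s, dt_s=0.001, ke0=None):
    """Independent explicit-Euler integrator used as a brute-force oracle.

    ``rate_fn(t_s)`` returns the infusion rate in mg/min at time t seconds.
    Returns (t_s, a1, a2, a3, ce) arrays sampled every step.
    """
    ke0 = ke0 if ke0 is not None else params.ke0
    n = int(round(duration_s / dt_s))
    dt_min = dt_s / 60.0
    a1 = a2 = a3 = ce = 0.0
    out = np.empty((n + 1, 5))
    out[0] = (0.0, a1, a2, a3, ce)
    for i in range(n):
        t = i * dt_s
        r = rate_fn(t)
        da1 = r - (params.k10 + params.k12 + params.k13) * a1 + params.k21 * a2 + params.k31 * a3
        da2 = params.k12 * a1 - params.k21 * a2
        da3 = params.k13 * a1 - params.k31 * a3
        dce = ke0 * (a1 / params.V1 - ce)
        a1 += da1 * dt_min
        a2 += da2 * dt_min
        a3 += da3 * dt_min
        ce += dce * dt_min
        out[i + 1] = (t + dt_s, a1, a2, a3, ce)
    return out
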