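import numpy as np
import pytest

import vrmotor as vm


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient cohort reused across read-only tests."""
    return vm.generate_cohort(vm.CohortConfig(n_patients=30, rng_seed=7))


@pytest.fixture(scope="session")
def coupling_cohort():
    """A larger cohort for correlation-sign checks."""
    return vm.generate_cohort(vm.CohortConfig(n_patients=500, rng_seed=11))


def make_tilt_series(episodes, rate=100.0, total_s=6.0, high=60.0, low=5.0):
    """Tilt trace with given (start_s, duration_s) exceedance episodes.

    Samples inside an episode sit at ``high`` degrees, all others at ``low``.
    """
    n = int(round(total_s * rate))
    t = np.arange(n) / rate
    tilt = np.full(n, low)
    for start, dur in episodes:
        tilt[(t >= start) & (t < start + dur)] = high
    return t, tilt


def brute_force_adl_score(t, tilt, threshold_deg, drain_s, n_cylinders=10):
    """Per-sample event simulation of the mug: accumulate exceedance time,
    drain one cylinder whenever a full quantum has elapsed."""
    acc = 0.0
    cylinders = n_cylinders
    for i in range(len(t) - 1):
        if tilt[i] > threshold_deg:
            acc += t[i + 1] - t[i]
            while acc >= drain_s - 1e-12 and cylinders > 0:
                acc -= drain_s
                cylinders -= 1
    return cylinders
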