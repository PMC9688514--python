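import numpy as np
import pytest

from carkin import (
    DoseSchedule,
    SyntheticCohortConfig,
    generate_cohort,
    reference_parameters,
    simulate,
)


@pytest.fixture(scope="session")
def ref_kp():
    """Timescale-separated reference parameter set."""
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_traj(ref_kp):
    """Reference trajectory: 1e8-cell dose into a 1e7-cell tumor, one year."""
    return simulate(ref_kp, DoseSchedule.single(1e8), T0=1e7,
                    t_end=400.0, dt=1e-3, grid=0.05)


@pytest.fixture(scope="session")
def dense_sampling(ref_traj):
    """Densely sampled, detectable observations of the reference trajectory."""
    days = np.concatenate([
        np.arange(0.25, 6.0, 0.25),
        np.arange(6.0, 14.0, 0.5),
        np.arange(14.0, 29.0, 1.0),
        np.arange(30.0, 91.0, 3.0),
        np.arange(95.0, 366.0, 5.0),
    ])
    values = np.interp(days, ref_traj.times, ref_traj.C)
    keep = values > 2.5e6
    return days[keep], values[keep]


@pytest.fixture(scope="session")
def cohort6():
    """Small mixed cohort for pipeline-level tests."""
    cfg = SyntheticCohortConfig(n_patients=6, seed=7)
    records, truth = generate_cohort(cfg)
    return cfg, records, truth
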