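import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def times_ms():
    return -200.0 + np.arange(701)


@pytest.fixture
def burst_recording():
    """One subject with a non-phase-locked 40 Hz burst over 1/f noise."""
    from epiosc.cohort import CohortConfig, InducedBurstSpec, generate_subject

    cfg = CohortConfig(
        n_control=1,
        n_patient=1,
        bursts=(InducedBurstSpec("NBG", 40.0, 100.0, 200.0, 1.0),),
        noise_scale=0.2,
        seed=11,
    )
    return generate_subject(cfg, "control", 11)
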