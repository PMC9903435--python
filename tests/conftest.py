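import numpy as np
import pytest

from survfusion import CohortConfig, make_records, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival_instance(rng, n, max_time=100.0, tie_prob=0.2):
    """A small random censored-survival instance with occasional ties."""
    if rng.random() < tie_prob:
        times = rng.integers(1, max(3, n // 2), size=n).astype(float)
    else:
        times = rng.uniform(1.0, max_time, size=n)
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    return times, events


@pytest.fixture
def small_clinical_cohort():
    """Clinical-only synthetic cohort shared by training-level tests."""
    cfg = CohortConfig(n_subjects=500, seed=42, image_signal_weight=0.0)
    return simulate_cohort(cfg, with_volumes=False)


@pytest.fixture
def records_factory():
    return make_records
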