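import numpy as np
import pytest

from pdmotion.config import CohortConfig, NetworkConfig, StftConfig
from pdmotion.preprocess import preprocess_cohort
from pdmotion.simulate import simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stft_cfg():
    return StftConfig()


@pytest.fixture(scope="session")
def reduced_net_cfg():
    return NetworkConfig.reduced()


def desk_cohort_config(n_subjects: int, seed: int, **over) -> CohortConfig:
    """Desk-scale cohort: short rounds, same signal model and protocol shape."""
    kw = dict(n_subjects=n_subjects, round_duration_s=60.0,
              session_duration_s=120.0, exam_duration_s=5.0, seed=seed)
    kw.update(over)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject desk-scale cohort of recordings (mixed protocol)."""
    return simulate_cohort(desk_cohort_config(6, seed=7))


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    """Filtered, segmented windows of the six-subject cohort."""
    return preprocess_cohort(small_cohort)
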