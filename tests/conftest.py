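import numpy as np
import pytest

from gutsound import CohortConfig, DetectorConfig, generate_cohort
from gutsound.pipeline import cohort_feature_matrix


def small_config(**overrides) -> CohortConfig:
    base = dict(n_ibs=3, n_healthy=3, seed=11, fasted_duration=60.0,
                fed_duration=20.0, sample_rate=8000.0)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def detector() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture(scope="session")
def tiny_cohort_features():
    """Feature matrix of a small separated cohort, shared across tests."""
    cfg = small_config(n_ibs=6, n_healthy=6, seed=21)
    cohort = generate_cohort(cfg)
    return cohort_feature_matrix(cohort)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
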