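import numpy as np
import pytest
from hypothesis import settings

from mpcmap import SimulationConfig, make_ground_truth, pipeline

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

#: the fixed study seed used by all cohort-level fixtures
STUDY_SEED = 5


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def gt_left(config):
    return make_ground_truth(config, "L")


@pytest.fixture(scope="session")
def memory_cohort(config):
    """Full memory cohort (n=24, default SNR) on the left hemisphere."""
    return pipeline.simulate_memory_cohort(config, "L")


@pytest.fixture(scope="session")
def memory_cohort_high_snr():
    """High-SNR memory cohort for peak-geometry checks."""
    cfg = SimulationConfig(seed=STUDY_SEED, sigma=0.2)
    return pipeline.simulate_memory_cohort(cfg, "L")


@pytest.fixture(scope="session")
def null_cohort():
    """Planted-null memory cohort (all amplitudes zero)."""
    cfg = SimulationConfig(seed=STUDY_SEED, amp=0.0, familiarity_boost=0.0)
    return pipeline.simulate_memory_cohort(cfg, "L")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
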