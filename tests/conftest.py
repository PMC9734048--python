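import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted cohort shared by the slower integration tests."""
    from neuroflex import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_tdc=3, n_adhd_unmedicated=3, n_adhd_medicated=2,
        n_regions=20, n_timepoints=60, master_seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
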