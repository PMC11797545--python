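import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def worked_composition():
    """Exact geometric age composition: counts halve each year (S = 0.5)."""
    from otodem import AgeComposition
    return AgeComposition(ages=(9, 10, 11, 12, 13), counts=(32, 16, 8, 4, 2),
                          start_age=9)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Slow-growth cohort with every noise source switched off."""
    from otodem import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_fish=500, Z_true=0.2, seed=99, G_true=0.8,
                           length_cv=0.0, otolith_noise_cv=0.0)
    return simulate_cohort(cfg)
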