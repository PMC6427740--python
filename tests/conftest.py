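import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def desk_dataset():
    """One desk-scale synthetic dataset shared across tests (read-only)."""
    from evomorbid.synthetic import SyntheticConfig, generate_dataset
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A very small dataset for fast pipeline tests."""
    from evomorbid.synthetic import SyntheticConfig, generate_dataset
    cfg = SyntheticConfig(n_foods=6, n_contaminants=10, n_regions=2,
                          n_weeks=30, observed_fraction=0.3, n_active=4,
                          seed=5)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
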