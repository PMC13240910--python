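import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soldissect as sd

settings.register_profile(
    "soldissect",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("soldissect")


@pytest.fixture(scope="session")
def tables():
    return sd.load_default_tables()


@pytest.fixture(scope="session")
def small_synthetic_matrix():
    """Calibrated synthetic sample, small enough for fast statistics."""
    cfg = sd.default_config(n_soluble=400, n_insoluble=400, seed=7)
    return sd.extract_features(sd.sample_dataset(cfg))


@pytest.fixture(scope="session")
def default_synthetic_matrix():
    """One draw at the generator's default size (5,000 per class)."""
    cfg = sd.default_config(seed=11)
    return sd.extract_features(sd.sample_dataset(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
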