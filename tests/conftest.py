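import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20170506)


@pytest.fixture
def two_class_data(rng):
    """Well-separated 2-class bivariate sample with known parameters."""
    n = 2000
    labels = rng.random(n) < 0.4
    spt = np.where(labels, rng.normal(0.35, 0.08, n), rng.normal(0.78, 0.10, n))
    fst = np.where(labels, rng.normal(170.0, 25.0, n), rng.normal(70.0, 25.0, n))
    params = {
        "weights": (0.4, 0.6),
        "means": ((0.35, 170.0), (0.78, 70.0)),
        "sds": ((0.08, 25.0), (0.10, 25.0)),
    }
    return np.column_stack([spt, fst]), labels, params
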