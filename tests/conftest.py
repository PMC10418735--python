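import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromlip import load_fixture_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dataset():
    """The bundled 28-compound study dataset."""
    return load_fixture_dataset()


def ols_normal_equations(x, y):
    """Independent OLS oracle: solve the 2x2 normal equations directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xtx = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    xty = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(xtx, xty)
    return intercept, slope
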