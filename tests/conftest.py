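import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cutpointsim import DiagnosticDataset, get_scenario  # noqa: E402

#: Printed reference values for the analytic density crossing points.
CROSSING_POINTS = {
    "scenario1": 9.20041,
    "scenario2": 7.47228,
    "scenario3": 5.10873,
    "scenario4": 13.4333,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def toy_dataset():
    """Four values, the top two diseased; cut-off 3 separates perfectly."""
    return DiagnosticDataset([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])


@pytest.fixture
def scenario1():
    return get_scenario("scenario1")


def random_small_dataset(rng, min_n=6, max_n=60):
    """A random two-class dataset for oracle comparisons."""
    n = int(rng.integers(min_n, max_n + 1))
    n_d = int(rng.integers(1, n))
    values = rng.uniform(0.5, 30.0, size=n)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_d, replace=False)] = 1
    return DiagnosticDataset(values, labels)
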