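import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synpid import JointDistribution, gate_distribution

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gates():
    return {
        name: gate_distribution(name)
        for name in ("xor", "and", "copy_x1", "redundant_copy", "parity3")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20231117)


def make_dist(arr, names=("X1", "X2", "Y")):
    supports = {n: tuple(range(s)) for n, s in zip(names, arr.shape)}
    return JointDistribution(names, supports, arr)


@pytest.fixture(scope="session")
def small_shapes():
    return [(2, 2, 2), (3, 3, 4), (4, 4, 5), (2, 3, 5), (4, 2, 3), (3, 2, 2)]
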