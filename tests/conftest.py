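import numpy as np
import pytest

import coalsky as ck
from coalsky.simulate import CONSTANT_TRUTH, simulate_genealogy


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture
def two_tip():
    """Isochronous pair coalescing at t = 1.5."""
    return ck.read_genealogy("(A:1.5,B:1.5);", {"A": 0.0, "B": 0.0})


@pytest.fixture
def two_tip_hetero():
    """Tips at ages 0 and 1, coalescing at t = 2."""
    return ck.read_genealogy("(A:2,B:1);", {"A": 0.0, "B": 1.0})


@pytest.fixture
def three_tip():
    """Isochronous triple with coalescences at t = 1 and t = 2."""
    return ck.read_genealogy("((A:1,B:1):1,C:2);", {"A": 0.0, "B": 0.0, "C": 0.0})


@pytest.fixture(scope="session")
def genealogy36():
    """One 36-tip isochronous genealogy simulated under the constant truth."""
    rng = np.random.default_rng(36036)
    return simulate_genealogy(np.zeros(36), CONSTANT_TRUTH, rng)


def random_genealogy(seed: int, n: int | None = None, hetero: bool = False):
    """Small random genealogy for property tests."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(2, 12))
    ages = rng.uniform(0.0, 500.0, size=n) if hetero else np.zeros(n)
    traj = ck.DemographicTrajectory([0.0, 300.0], [800.0, 2000.0])
    return simulate_genealogy(ages, traj, rng)
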