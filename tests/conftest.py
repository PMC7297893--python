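import numpy as np
import pytest

from renyifs import (
    JointDistribution,
    PlantedTableSpec,
    SessionSpec,
    generate_planted_table,
    generate_session,
)


def random_joint(rng: np.random.Generator, n_x: int = 3, n_y: int = 4) -> JointDistribution:
    """A random strictly-positive joint distribution."""
    p = rng.random((n_x, n_y)) + 1e-3
    p /= p.sum()
    # renormalize exactly so the mass invariant holds to 1e-12
    p = p / p.sum()
    return JointDistribution(p)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_table():
    """3 informative of 50 features, d=3, 100 trials/class, 4 classes."""
    return generate_planted_table(PlantedTableSpec(seed=7))


@pytest.fixture(scope="session")
def small_session():
    """A reduced 2-run session for fast structural tests."""
    spec = SessionSpec(runs_per_session=2, seed=5)
    return generate_session(spec)
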