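import numpy as np
import pytest

import chemoviro as cv


@pytest.fixture
def dim():
    """Published dimensional parameter set."""
    return cv.table1()


@pytest.fixture
def nd():
    """Published parameters, nondimensional, default (per-1e6) beta reading."""
    return cv.table1_nondim()


@pytest.fixture
def nd_cell():
    """Published parameters, nondimensional, per-cell beta reading
    (the reading under which the simulation figures reproduce)."""
    return cv.table1_nondim(beta_convention=cv.BETA_PER_CELL)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_nondim(rng, viro_active=True):
    """Admissible random nondimensional parameter draw with O(0.01..10) rates.

    Ranges keep every eigenvalue scale resolvable by a fixed-step
    integrator and every equilibrium decently hyperbolic, so that
    classification can be cross-checked by perturbation simulation.
    """
    return cv.NondimParams(
        alpha=rng.uniform(0.2, 1.0),
        beta=rng.uniform(0.1, 2.0) if viro_active else 0.0,
        delta0=rng.uniform(0.02, 0.5),
        delta1=rng.uniform(0.02, 0.5),
        b=rng.uniform(2.0, 20.0) if viro_active else 0.0,
        gamma=rng.uniform(0.05, 0.5),
        phi=rng.uniform(0.5, 5.0),
        psi=rng.uniform(1.0, 10.0),
        a=1.0,
    )
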