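import math

import numpy as np
import pytest

import fibersurf as fs

# boundary geometry used throughout: disks of radius 1 separated by 1.25
R, L = 1.0, 1.25
HALF = L / 2.0
RHO = math.hypot(R, HALF)  # single-sphere radius 1.17925


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic catalog of analytic oracle shapes."""
    return fs.fixture_suite(seed=0, R=R, L=L)


@pytest.fixture(scope="session")
def sphere_solution():
    """Shooting solve at the single-sphere landmark (mu0 = 30 deg < 58 deg)."""
    res = fs.solve_kappa(RHO, 30.0, R=R, L=L)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def generic_solution():
    """A necked equilibrium away from all closed forms."""
    res = fs.solve_kappa(0.6, 35.0, R=R, L=L)
    assert res.converged
    return res
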