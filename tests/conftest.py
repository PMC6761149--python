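"""Shared fixtures: analytic phantoms and standard grids."""

import numpy as np
import pytest

from oligosaxs import ScatteringProfile
from oligosaxs.synthetic import ball_model, default_q_grid, sphere_curve

SPHERE_RG_FACTOR = np.sqrt(3.0 / 5.0)  # Rg of a uniform ball of radius R


@pytest.fixture
def q_grid():
    return default_q_grid()


@pytest.fixture
def sphere30():
    """Noiseless homogeneous-sphere curve, R = 30 A, I0 = 7, to qR = 25."""
    q = np.linspace(1e-3, 25.0 / 30.0, 400)
    return sphere_curve(30.0, 7.0, q)


@pytest.fixture
def sphere40():
    """Noiseless sphere, R = 40 A, on a moderate grid (P(r) work)."""
    q = np.linspace(1e-3, 0.3, 150)
    return sphere_curve(40.0, 5.0, q)


@pytest.fixture
def ball2000():
    """2,000 uniform point scatterers in a ball of radius 30 A."""
    return ball_model(30.0, 2000, seed=1)


@pytest.fixture
def exp_profile():
    """Exact Guinier-law curve: I = 7 exp(-q^2 23^2 / 3)."""
    q = np.linspace(1e-3, 0.06, 60)
    return ScatteringProfile(q=q, I=7.0 * np.exp(-q ** 2 * 23.0 ** 2 / 3.0))
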