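"""Shared fixtures: electrolyte conditions, coarse PB surfaces (session
scoped, built once), and fast analytic effective-charge surfaces for
statistical tests that do not need the PB solver."""

import numpy as np
import pytest

from helixq.electrolyte import ElectrolyteConditions, SlitDevice
from helixq.pb import EffectiveChargeSurface, SolverSpec, build_charge_surface


@pytest.fixture(scope="session")
def licl_conditions():
    return ElectrolyteConditions(salt_species="LiCl", c=1.23e-3)


@pytest.fixture(scope="session")
def device():
    return SlitDevice()


@pytest.fixture(scope="session")
def pb_surfaces(licl_conditions):
    """Coarse (6x6) PB effective-charge surfaces for n = 30, 40, 60."""
    b_grid = np.linspace(2.0, 5.0, 6)
    r_grid = np.linspace(6.0, 30.0, 6)
    return {
        n: build_charge_surface(n, b_grid, r_grid, licl_conditions)
        for n in (30, 40, 60)
    }


# Analytic surrogate surfaces: smooth, monotone, with deliberately
# non-parallel ratio gradients so that (b, r) are jointly identifiable.
_ETA_PARAMS = {
    30: (0.45, 0.18, 0.30),
    40: (0.42, 0.25, 0.05),
    60: (0.38, 0.30, 0.15),
}


def analytic_eta(n, b, r):
    s, u, v = _ETA_PARAMS[n]
    return s * np.exp(u * (np.asarray(b) - 3.4) / 3.0 + v * (np.asarray(r) - 10.5) / 24.0)


@pytest.fixture(scope="session")
def analytic_surfaces(licl_conditions):
    b_grid = np.linspace(2.0, 5.0, 31)
    r_grid = np.linspace(6.0, 30.0, 49)
    bb, rr = np.meshgrid(b_grid, r_grid, indexing="ij")
    surfaces = {}
    for n in (30, 40, 60):
        q_net = -2.0 * (n - 1)
        eta = analytic_eta(n, bb, rr)
        surfaces[n] = EffectiveChargeSurface(
            n, licl_conditions, b_grid, r_grid, q_net * eta, eta
        )
    return surfaces


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
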