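"""Electrolyte and slit-device physics.

Screening length, Bjerrum length and the slit midplane potential in
thermal units (k_B T / e). All lengths are nanometres unless noted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    EPSILON_0,
    T_REF,
    WATER_EPS_R,
)
from .errors import InvalidInputError

__all__ = [
    "ElectrolyteConditions",
    "SlitDevice",
    "debye_length",
    "bjerrum_length",
    "midplane_potential",
]


@dataclass(frozen=True)
class ElectrolyteConditions:
    """A symmetric 1:1 electrolyte at a given concentration and temperature.

    Parameters
    ----------
    salt_species:
        Label for the salt (e.g. ``"LiCl"``).
    c:
        Molar salt concentration (mol/L). Ionic strength is taken equal
        to ``c`` for the 1:1 salts in scope.
    T:
        Absolute temperature (K).
    valence:
        Ion valence; only 1 is supported.
    a_H:
        Hydrated cation radius (Angstrom), optional.
    """

    salt_species: str
    c: float
    T: float = T_REF
    valence: int = 1
    a_H: float | None = None

    def __post_init__(self):
        if self.c <= 0:
            raise InvalidInputError(f"concentration must be positive, got {self.c}")
        if self.T <= 0:
            raise InvalidInputError(f"temperature must be positive, got {self.T}")
        if self.valence != 1:
            raise InvalidInputError(
                f"only 1:1 electrolytes are supported, got valence {self.valence}"
            )
        if self.a_H is not None and self.a_H < 0:
            raise InvalidInputError(f"hydrated radius must be >= 0, got {self.a_H}")


@dataclass(frozen=True)
class SlitDevice:
    """Parallel-plate nanoslit with a nanostructured trap pocket.

    Attributes
    ----------
    h:
        Slit half height (nm).
    l_s:
        Pocket radius (nm).
    d:
        Pocket depth (nm).
    phi_s:
        Wall surface potential in thermal units (k_B T / e); non-positive
        for the silica walls in scope.
    h_e:
        One-sigma uncertainty of the slit half height (nm).
    """

    h: float = 37.5
    l_s: float = 250.0
    d: float = 150.0
    phi_s: float = -2.8
    h_e: float = 0.5

    def __post_init__(self):
        if self.h <= 0:
            raise InvalidInputError(f"half height must be positive, got {self.h}")
        if self.l_s <= 0:
            raise InvalidInputError(f"pocket radius must be positive, got {self.l_s}")
        if self.d < 0:
            raise InvalidInputError(f"pocket depth must be >= 0, got {self.d}")
        if self.phi_s > 0:
            raise InvalidInputError(
                f"wall potential must be <= 0 for silica, got {self.phi_s}"
            )


def debye_length(conditions: ElectrolyteConditions) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte.

    kappa^-1 = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I)) with ionic
    strength I equal to the molar salt concentration.
    """
    I_m3 = conditions.c * 1e3 * AVOGADRO  # ions per m^3 per species
    k2 = 2.0 * ELEMENTARY_CHARGE**2 * I_m3 / (
        WATER_EPS_R * EPSILON_0 * BOLTZMANN * conditions.T
    )
    return 1e9 / math.sqrt(k2)


def bjerrum_length(T: float = T_REF, relative_permittivity: float = WATER_EPS_R) -> float:
    """Bjerrum length (nm): e^2 / (4 pi eps_r eps_0 k_B T)."""
    if T <= 0:
        raise InvalidInputError(f"temperature must be positive, got {T}")
    if relative_permittivity <= 0:
        raise InvalidInputError(
            f"permittivity must be positive, got {relative_permittivity}"
        )
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * relative_permittivity * EPSILON_0 * BOLTZMANN * T
    )
    return lb_m * 1e9


def midplane_potential(device: SlitDevice, conditions: ElectrolyteConditions) -> float:
    """Midplane potential of the slit, phi_m = 2 phi_s exp(-kappa h).

    Superposition of the two wall potentials; valid for kappa*h > 1.
    Returns the potential in thermal units (k_B T / e).
    """
    kappa_h = device.h / debye_length(conditions)
    if kappa_h <= 1.0:
        warnings.warn(
            f"kappa*h = {kappa_h:.3g} <= 1: wall-potential superposition is "
            "a poor approximation in this regime",
            stacklevel=2,
        )
    return 2.0 * device.phi_s * math.exp(-kappa_h)
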