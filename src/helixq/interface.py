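"""Shared-slope linear model of measured helical radius versus hydrated
cation radius: r_m = r_0(species) + k * a_H with one common slope k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InvalidInputError

__all__ = ["RadiusMeasurement", "InterfaceFit", "fit_shared_slope", "load_radius_table"]


@dataclass(frozen=True)
class RadiusMeasurement:
    """Measured helix radius for one species in one salt (Angstrom)."""

    species: str
    salt: str
    a_H: float
    r_m: float
    sem: float

    def __post_init__(self):
        if self.sem <= 0:
            raise InvalidInputError(f"sem must be positive, got {self.sem}")
        if self.a_H < 0:
            raise InvalidInputError(f"a_H must be >= 0, got {self.a_H}")


@dataclass
class InterfaceFit:
    """Per-species intercepts, shared slope, and their covariance."""

    r0_by_species: dict
    k: float
    covariance: np.ndarray  # order: intercepts (sorted species), then k
    chi2: float
    dof: int
    species_order: list

    def r0_sigma(self, species: str) -> float:
        i = self.species_order.index(species)
        return float(np.sqrt(self.covariance[i, i]))

    @property
    def k_sigma(self) -> float:
        return float(np.sqrt(self.covariance[-1, -1]))


def fit_shared_slope(points, species_set=None, weighted: bool = True) -> InterfaceFit:
    """Weighted least squares with per-species intercepts and one slope.

    Weights are 1/sem^2 (set ``weighted=False`` for an unweighted fit);
    the parameter covariance comes from the normal equations. All ``a_H``
    equal makes the design rank deficient and is an error.
    """
    points = list(points)
    if species_set is None:
        species_set = sorted({p.species for p in points})
    else:
        species_set = sorted(species_set)
        extra = {p.species for p in points} - set(species_set)
        if extra:
            raise InvalidInputError(f"points contain unknown species: {sorted(extra)}")
    for sp in species_set:
        if sum(p.species == sp for p in points) < 2:
            raise InvalidInputError(f"need >= 2 points for species {sp!r}")
    a_h = np.array([p.a_H for p in points])
    if np.ptp(a_h) == 0:
        raise DegenerateDesignError("all a_H equal: slope is not identifiable")

    n_sp = len(species_set)
    design = np.zeros((len(points), n_sp + 1))
    for row, p in enumerate(points):
        design[row, species_set.index(p.species)] = 1.0
        design[row, -1] = p.a_H
    y = np.array([p.r_m for p in points])
    w = np.array([1.0 / p.sem**2 for p in points]) if weighted else np.ones(len(points))

    xtw = design.T * w
    normal = xtw @ design
    if np.linalg.matrix_rank(normal) < n_sp + 1:
        raise DegenerateDesignError("rank-deficient design matrix")
    cov = np.linalg.inv(normal)
    beta = cov @ (xtw @ y)
    resid = y - design @ beta
    chi2 = float((w * resid**2).sum())
    dof = len(points) - (n_sp + 1)
    return InterfaceFit(
        r0_by_species={sp: float(beta[i]) for i, sp in enumerate(species_set)},
        k=float(beta[-1]),
        covariance=cov,
        chi2=chi2,
        dof=dof,
        species_order=species_set,
    )


def load_radius_table(path):
    """Read a radius table (species, salt, a_H_A, r_m_A, sem_A)."""
    df = pd.read_csv(path)
    required = {"species", "salt", "a_H_A", "r_m_A", "sem_A"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"radius table missing columns: {sorted(missing)}")
    return [
        RadiusMeasurement(
            species=row.species,
            salt=row.salt,
            a_H=float(row.a_H_A),
            r_m=float(row.r_m_A),
            sem=float(row.sem_A),
        )
        for row in df.itertuples()
    ]
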