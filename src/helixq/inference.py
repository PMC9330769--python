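"""Three-length helix-geometry inference.

Pairwise ratios of background-corrected effective charges for three
fragment lengths cancel the multiplicative apparatus factor f_M; the
ratios are compared with tabulated PB effective-charge surfaces to give
a probability-weighted manifold over (rise per basepair, radius), whose
refined mode yields the geometry estimate. f_M is then recovered
self-consistently from the individual measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    BoundarySolutionError,
    DegenerateManifoldError,
    DegenerateMeasurementError,
    InconsistentDataError,
    InvalidInputError,
    SignInconsistencyError,
)
from .pb import EffectiveChargeSurface

__all__ = [
    "MeasuredCharge",
    "CorrectionFactors",
    "RatioObservable",
    "BRManifold",
    "GeometryEstimate",
    "ratio_observables",
    "build_manifold",
    "estimate_geometry",
    "solve_fM",
    "load_measurements",
]

#: Default dye contribution to the measured charge (e): the labels add
#: +0.5 e against the negative backbone, so the background-corrected
#: molecular charge is q_m - 0.5 e. Flip the sign via the f_A argument
#: of the individual operations if a different convention is needed.
DEFAULT_F_A = 0.5


@dataclass(frozen=True)
class MeasuredCharge:
    """One fragment's measured effective charge (signed, in e)."""

    species: str
    n_bp: int
    q_m: float
    sigma: float
    salt: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidInputError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class CorrectionFactors:
    """Apparatus corrections: q_m = f_M * q_eff + f_A, f_M = f_phi * f_ion."""

    f_A: float
    f_phi: float = 1.0
    f_ion: float = 1.0

    @property
    def f_M(self) -> float:
        return self.f_phi * self.f_ion

    def __post_init__(self):
        if self.f_M <= 0:
            raise InvalidInputError("f_M = f_phi * f_ion must be positive")


@dataclass(frozen=True)
class RatioObservable:
    """Dye-corrected charge ratio rho = (q_i - f_A) / (q_j - f_A)."""

    n_i: int
    n_j: int
    value: float
    sigma: float


def ratio_observables(measurements, f_A: float = DEFAULT_F_A, with_covariance=False):
    """Pairwise charge ratios that eliminate the multiplicative factor.

    Expects exactly three measurements of one species/salt with distinct
    fragment lengths. The two ratios share the longest fragment as the
    denominator. Uncertainties propagate to first order:
    sigma_rho^2 = rho^2 [ (s_i/(q_i-f_A))^2 + (s_j/(q_j-f_A))^2 ].

    With ``with_covariance`` the full 2x2 first-order covariance of the
    two ratios (correlated through the shared denominator) is returned
    alongside, for the covariance-aware manifold mode.
    """
    ms = sorted(measurements, key=lambda m: m.n_bp)
    if len(ms) != 3 or len({m.n_bp for m in ms}) != 3:
        raise InvalidInputError("need exactly three measurements with distinct n_bp")
    if len({(m.species, m.salt) for m in ms}) != 1:
        raise InvalidInputError("measurements must share species and salt")
    for m in ms:
        if abs(m.q_m) <= abs(f_A):
            raise DegenerateMeasurementError(
                f"|q_m| = {abs(m.q_m)} <= |f_A| = {abs(f_A)} for n={m.n_bp}"
            )
    denom = ms[2]
    out = []
    for num in ms[:2]:
        qi, qj = num.q_m - f_A, denom.q_m - f_A
        rho = qi / qj
        sig = abs(rho) * math.hypot(num.sigma / qi, denom.sigma / qj)
        out.append(RatioObservable(n_i=num.n_bp, n_j=denom.n_bp, value=rho, sigma=sig))
    if not with_covariance:
        return out
    qj = denom.q_m - f_A
    cov = np.array(
        [
            [out[0].sigma ** 2, out[0].value * out[1].value * (denom.sigma / qj) ** 2],
            [out[0].value * out[1].value * (denom.sigma / qj) ** 2, out[1].sigma ** 2],
        ]
    )
    return out, cov


@dataclass
class BRManifold:
    """Normalized probability weights over the (b, r) grid."""

    b_grid: np.ndarray
    r_grid: np.ndarray
    weights: np.ndarray  # (len(b), len(r)), sums to 1
    chi2: np.ndarray  # per-node ratio misfit diagnostics

    def __post_init__(self):
        s = self.weights.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-10):
            raise InvalidInputError("manifold weights must be normalized")
        if (self.weights < 0).any():
            raise InvalidInputError("manifold weights must be non-negative")

    def entropy(self) -> float:
        w = self.weights[self.weights > 0]
        return float(-(w * np.log(w)).sum())


def build_manifold(
    ratios,
    surfaces: dict,
    b_grid=None,
    r_grid=None,
    ratio_covariance=None,
) -> BRManifold:
    """Gaussian-weighted manifold over (b, r) from the ratio observables.

    ``surfaces`` maps fragment length to its
    :class:`~helixq.pb.EffectiveChargeSurface`. By default the manifold
    lives on the (shared) surface node grid; passing finer ``b_grid`` /
    ``r_grid`` evaluates the surfaces' interpolants instead. Per-node
    weights are products of independent ratio Gaussians, or a joint
    Gaussian when the 2x2 ``ratio_covariance`` (shared-denominator
    correlation) is supplied.
    """
    lengths = {r.n_i for r in ratios} | {r.n_j for r in ratios}
    for n in lengths:
        if n not in surfaces:
            raise InvalidInputError(f"no effective-charge surface for n_bp = {n}")
    ref = surfaces[next(iter(lengths))]
    on_nodes = b_grid is None and r_grid is None
    if on_nodes:
        b_grid, r_grid = ref.b_grid, ref.r_grid
        for n in lengths:
            s = surfaces[n]
            if not (
                np.array_equal(s.b_grid, b_grid) and np.array_equal(s.r_grid, r_grid)
            ):
                raise InvalidInputError("surfaces must share (b, r) grids")
        q_tab = {n: surfaces[n].q_eff_values for n in lengths}
    else:
        b_grid = np.asarray(b_grid if b_grid is not None else ref.b_grid, dtype=float)
        r_grid = np.asarray(r_grid if r_grid is not None else ref.r_grid, dtype=float)
        q_tab = {n: surfaces[n].q_eff_grid(b_grid, r_grid) for n in lengths}

    for ratio in ratios:
        if ratio.sigma <= 0:
            raise InvalidInputError("ratio sigma must be positive")
    if ratio_covariance is not None:
        if len(ratios) != 2:
            raise InvalidInputError("ratio_covariance requires exactly two ratios")
        prec = np.linalg.inv(np.asarray(ratio_covariance, dtype=float))
        d0 = q_tab[ratios[0].n_i] / q_tab[ratios[0].n_j] - ratios[0].value
        d1 = q_tab[ratios[1].n_i] / q_tab[ratios[1].n_j] - ratios[1].value
        chi2 = prec[0, 0] * d0**2 + 2.0 * prec[0, 1] * d0 * d1 + prec[1, 1] * d1**2
    else:
        chi2 = np.zeros((len(b_grid), len(r_grid)))
        for ratio in ratios:
            model = q_tab[ratio.n_i] / q_tab[ratio.n_j]
            chi2 += ((model - ratio.value) / ratio.sigma) ** 2
    log_w = -0.5 * chi2
    log_w -= log_w.max()
    w = np.exp(log_w)
    total = w.sum()
    if not np.isfinite(total) or total <= 0 or chi2.min() > 5e5:
        raise InconsistentDataError(
            "measurements incompatible with the model grid (all weights underflow)"
        )
    return BRManifold(b_grid=b_grid, r_grid=r_grid, weights=w / total, chi2=chi2)


@dataclass(frozen=True)
class GeometryEstimate:
    """Refined manifold mode and curvature-based uncertainties."""

    b_m: float
    r_m: float
    sigma_b: float
    sigma_r: float
    f_M: float | None = None
    species: str = ""
    salt: str = ""
    valley_degenerate: bool = False


def _quadratic_patch(chi2_half, b_grid, r_grid, i, j, half):
    """Least-squares quadratic for 0.5*chi2 on a (2*half+1)^2 patch."""
    bs = b_grid[i - half : i + half + 1] - b_grid[i]
    rs = r_grid[j - half : j + half + 1] - r_grid[j]
    patch = chi2_half[i - half : i + half + 1, j - half : j + half + 1]
    bb, rr = np.meshgrid(bs, rs, indexing="ij")
    cols = [np.ones_like(bb), bb, rr, bb * rr, bb**2, rr**2]
    design = np.stack([c.ravel() for c in cols], axis=1)
    coef, *_ = np.linalg.lstsq(design, patch.ravel(), rcond=None)
    _, cb, cr, cbr, cbb, crr = coef
    hess = np.array([[2.0 * cbb, cbr], [cbr, 2.0 * crr]])
    grad = np.array([cb, cr])
    return grad, hess


def _check_ridge(chi2, tol=0.01, span_frac=0.6):
    """Structural ridge test: the near-minimum level set must be compact.

    A single charge ratio constrains (b, r) only to a curve, whose level
    set chi2 - min < tol spans the whole grid. Detected and reported,
    never silently resolved.
    """
    sel = chi2 - chi2.min() < tol
    ib, jb = np.nonzero(sel)
    nb, nr = chi2.shape
    if (np.ptp(ib) + 1) >= span_frac * nb or (np.ptp(jb) + 1) >= span_frac * nr:
        raise DegenerateManifoldError(
            "degenerate (ridge-like) manifold: the near-minimum set spans the "
            "grid; (b, r) are not jointly identifiable from the available ratios"
        )


def estimate_geometry(manifold: BRManifold) -> GeometryEstimate:
    """Mode of the manifold, refined by local quadratic interpolation.

    The weight-maximizing node is refined by a local quadratic fit to
    -ln(weight); uncertainties are the square roots of the diagonal of
    the local inverse Hessian. The fitting patch grows until the Hessian
    is positive definite; inside a curved, nearly flat valley
    (indefinite Hessian at every patch size) the estimate falls back to
    independent per-axis parabolic refinement and is flagged
    ``valley_degenerate``. A mode on the grid boundary and a true ridge
    (near-minimum level set spanning the grid) are errors, never silent
    results.
    """
    w = manifold.weights
    chi2 = manifold.chi2
    i, j = np.unravel_index(np.argmax(w), w.shape)
    nb, nr = w.shape
    if i in (0, nb - 1) or j in (0, nr - 1):
        raise BoundarySolutionError(
            f"manifold mode on the grid boundary at b={manifold.b_grid[i]:.3g}, "
            f"r={manifold.r_grid[j]:.3g}; widen the grid"
        )
    _check_ridge(chi2)
    half_chi2 = 0.5 * chi2
    for half in (1, 2, 3):
        if i - half < 0 or i + half >= nb or j - half < 0 or j + half >= nr:
            break
        grad, hess = _quadratic_patch(
            half_chi2, manifold.b_grid, manifold.r_grid, i, j, half
        )
        eigvals = np.linalg.eigvalsh(hess)
        if eigvals.min() > 0 and eigvals.min() / eigvals.max() > 1e-12:
            shift = np.linalg.solve(hess, -grad)
            db = manifold.b_grid[i + 1] - manifold.b_grid[i]
            dr = manifold.r_grid[j + 1] - manifold.r_grid[j]
            shift[0] = float(np.clip(shift[0], -half * db, half * db))
            shift[1] = float(np.clip(shift[1], -half * dr, half * dr))
            cov = np.linalg.inv(hess)
            return GeometryEstimate(
                b_m=float(manifold.b_grid[i] + shift[0]),
                r_m=float(manifold.r_grid[j] + shift[1]),
                sigma_b=float(math.sqrt(cov[0, 0])),
                sigma_r=float(math.sqrt(cov[1, 1])),
            )
    # Curved valley: the quadratic model is indefinite at all patch
    # sizes. Refine each axis independently through the mode node.
    db = manifold.b_grid[i + 1] - manifold.b_grid[i]
    dr = manifold.r_grid[j + 1] - manifold.r_grid[j]

    def _vertex(fm, f0, fp, h):
        denom = fm - 2.0 * f0 + fp
        if denom <= 0:
            return 0.0, float("inf")
        shift = 0.5 * (fm - fp) / denom * h
        return float(np.clip(shift, -h, h)), h * math.sqrt(1.0 / denom)

    sb_shift, sigma_b = _vertex(
        half_chi2[i - 1, j], half_chi2[i, j], half_chi2[i + 1, j], db
    )
    sr_shift, sigma_r = _vertex(
        half_chi2[i, j - 1], half_chi2[i, j], half_chi2[i, j + 1], dr
    )
    return GeometryEstimate(
        b_m=float(manifold.b_grid[i] + sb_shift),
        r_m=float(manifold.r_grid[j] + sr_shift),
        sigma_b=sigma_b,
        sigma_r=sigma_r,
        valley_degenerate=True,
    )


def solve_fM(
    measurements,
    surfaces: dict,
    estimate: GeometryEstimate,
    f_A: float = DEFAULT_F_A,
):
    """Self-consistent multiplicative factor at the estimated geometry.

    Inverse-variance-weighted mean of (q_m - f_A) / q_eff(b_m, r_m) over
    the three fragments; returns (f_M, per-fragment values, residual
    z-spread). A non-positive result raises
    :class:`SignInconsistencyError`.
    """
    vals, variances = [], []
    for m in measurements:
        q_eff = float(surfaces[m.n_bp].q_eff_at(estimate.b_m, estimate.r_m))
        if q_eff == 0.0:
            raise InvalidInputError(f"q_eff vanishes at the estimate for n={m.n_bp}")
        vals.append((m.q_m - f_A) / q_eff)
        variances.append((m.sigma / q_eff) ** 2)
    vals = np.asarray(vals)
    weights = 1.0 / np.asarray(variances)
    f_m = float((weights * vals).sum() / weights.sum())
    if f_m <= 0:
        raise SignInconsistencyError(
            f"recovered f_M = {f_m:.4g} <= 0: sign convention mismatch between "
            "measurements and surfaces"
        )
    spread = float(np.max(np.abs(vals - f_m) * np.sqrt(weights)))
    return f_m, vals, spread


def load_measurements(path) -> list:
    """Read a measurement table (species, salt, n_bp, q_m_e, sigma_e)."""
    df = pd.read_csv(path)
    required = {"species", "salt", "n_bp", "q_m_e", "sigma_e"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"measurement table missing columns: {sorted(missing)}")
    return [
        MeasuredCharge(
            species=row.species,
            salt=row.salt,
            n_bp=int(row.n_bp),
            q_m=float(row.q_m_e),
            sigma=float(row.sigma_e),
        )
        for row in df.itertuples()
    ]
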