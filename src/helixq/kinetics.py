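"""Escape-time kinetics: event extraction, dwell-time fitting, Kramers
conversion, and Brownian-dynamics simulation of trap escape.

Times are milliseconds, energies in k_B T, lengths in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

from .constants import BOLTZMANN, T_REF
from .electrolyte import SlitDevice
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    InvalidThresholdError,
    InvalidTimestepError,
)

__all__ = [
    "ResidenceTimeSet",
    "EscapeTimeEstimate",
    "WellDepth",
    "BDParams",
    "extract_residence_times",
    "fit_escape_time",
    "fit_escape_time_histogram",
    "kramers_well_depth",
    "simulate_escape_bd",
    "calibrate_prefactor",
    "effective_charge_from_energy",
    "stokes_einstein_diffusivity",
    "mean_first_passage_quadrature",
    "PrefactorMap",
]

#: Water viscosity at 298 K (Pa s).
WATER_VISCOSITY = 8.90e-4


@dataclass
class ResidenceTimeSet:
    """Censored single-molecule dwell times with detection metadata."""

    durations: np.ndarray  # ms
    t_min: float  # detection floor (ms)
    t_cycle: float  # camera cycle time (ms)
    trap_ids: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        if self.t_cycle <= 0:
            raise InvalidInputError(f"t_cycle must be positive, got {self.t_cycle}")
        if self.durations.size and self.durations.min() < self.t_min - 1e-9:
            raise InvalidInputError("all durations must be >= t_min")
        if self.trap_ids is not None:
            self.trap_ids = np.asarray(self.trap_ids)
            if len(self.trap_ids) != len(self.durations):
                raise InvalidInputError("trap_ids must match durations in length")

    @property
    def N(self) -> int:
        return len(self.durations)

    def to_csv(self, path):
        ids = self.trap_ids if self.trap_ids is not None else np.zeros(self.N, dtype=int)
        df = pd.DataFrame(
            {"trap_id": ids, "dt_ms": self.durations, "t_cycle_ms": self.t_cycle}
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, t_min=None):
        df = pd.read_csv(path, float_precision="round_trip")
        t_cycle = float(df["t_cycle_ms"].iloc[0])
        return cls(
            durations=df["dt_ms"].to_numpy(),
            t_min=t_cycle if t_min is None else t_min,
            t_cycle=t_cycle,
            trap_ids=df["trap_id"].to_numpy(),
        )


@dataclass(frozen=True)
class EscapeTimeEstimate:
    """Mean escape time from a truncated-exponential fit."""

    t_esc: float  # ms
    se: float  # ms
    N: int
    loglik: float


@dataclass(frozen=True)
class WellDepth:
    """Trap depth decomposition W = dF_elec + dF_fluc (k_B T)."""

    W: float
    dF_elec: float
    dF_fluc: float = 0.0

    def __post_init__(self):
        if not math.isclose(self.W, self.dF_elec + self.dF_fluc, rel_tol=1e-12, abs_tol=1e-12):
            raise InvalidInputError("W must equal dF_elec + dF_fluc")


def stokes_einstein_diffusivity(r_h_nm: float, T: float = T_REF) -> float:
    """Stokes-Einstein diffusion coefficient (nm^2/ms) for radius r_h (nm)."""
    if r_h_nm <= 0:
        raise InvalidInputError("hydrodynamic radius must be positive")
    d_m2s = BOLTZMANN * T / (6.0 * math.pi * WATER_VISCOSITY * r_h_nm * 1e-9)
    return d_m2s * 1e18 / 1e3  # m^2/s -> nm^2/ms


@dataclass
class BDParams:
    """Brownian-dynamics parameters; D follows Stokes-Einstein from r_H."""

    r_H: float  # nm
    dt: float  # ms
    seed: int
    n_walkers: int
    D: float = field(init=False)

    def __post_init__(self):
        self.D = stokes_einstein_diffusivity(self.r_H)
        if self.dt <= 0 or self.n_walkers < 1:
            raise InvalidInputError("dt and n_walkers must be positive")


# ---------------------------------------------------------------------------
# event extraction and dwell-time fitting
# ---------------------------------------------------------------------------


def extract_residence_times(trace, threshold, t_cycle):
    """Threshold an intensity trace into residence events.

    Maximal runs of consecutive above-threshold frames become events of
    duration (frame count) * t_cycle; runs touching either end of the
    trace are discarded as censored. The detection floor is one cycle.
    """
    trace = np.asarray(trace, dtype=float)
    if t_cycle <= 0:
        raise InvalidInputError("t_cycle must be positive")
    if trace.size and not (trace.min() < threshold < trace.max()):
        raise InvalidThresholdError(
            f"threshold {threshold} outside trace range "
            f"[{trace.min() if trace.size else 'nan'}, {trace.max() if trace.size else 'nan'}]"
        )
    above = trace > threshold
    # run-length encode
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    keep = (starts > 0) & (ends < len(trace))
    durations = (ends[keep] - starts[keep]) * t_cycle
    return ResidenceTimeSet(durations=durations, t_min=t_cycle, t_cycle=t_cycle)


def fit_escape_time(events: ResidenceTimeSet) -> EscapeTimeEstimate:
    """Exact MLE of the mean of a left-truncated exponential.

    For durations observed only above the floor ``t_min`` the likelihood
    is maximized at t_esc = mean(dt) - t_min, with standard error
    t_esc / sqrt(N).
    """
    if events.N < 10:
        raise InsufficientDataError(f"need >= 10 events, got {events.N}")
    t_esc = float(events.durations.mean() - events.t_min)
    if t_esc <= 0:
        raise DegenerateDataError("non-positive fitted escape time")
    n = events.N
    loglik = -n * (math.log(t_esc) + 1.0)
    return EscapeTimeEstimate(t_esc=t_esc, se=t_esc / math.sqrt(n), N=n, loglik=loglik)


def fit_escape_time_histogram(events: ResidenceTimeSet, n_bins: int = 30):
    """Secondary cross-check: least-squares fit of log binned density.

    Weighted linear regression of log counts against bin centers; returns
    an :class:`EscapeTimeEstimate` (loglik set to NaN).
    """
    if events.N < 10:
        raise InsufficientDataError(f"need >= 10 events, got {events.N}")
    dt = events.durations
    counts, edges = np.histogram(dt, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        raise DegenerateDataError("too few occupied histogram bins")
    y = np.log(counts[mask])
    w = counts[mask].astype(float)  # Poisson: var(log n) ~ 1/n
    coef = np.polyfit(centers[mask], y, 1, w=np.sqrt(w))
    slope = coef[0]
    if slope >= 0:
        raise DegenerateDataError("non-decaying histogram")
    t_esc = -1.0 / slope
    return EscapeTimeEstimate(
        t_esc=t_esc, se=t_esc / math.sqrt(events.N), N=events.N, loglik=float("nan")
    )


def kramers_well_depth(t_esc: float, t_0: float) -> float:
    """Well depth W = ln(t_esc / t_0) in k_B T.

    Valid for deep wells; W <= 4 triggers a validity warning.
    """
    if t_esc <= 0 or t_0 <= 0:
        raise InvalidInputError("t_esc and t_0 must be positive")
    w = math.log(t_esc / t_0)
    if w <= 4.0:
        warnings.warn(
            f"W = {w:.3g} k_BT <= 4: outside the validity regime of the "
            "exponential escape-time relation",
            stacklevel=2,
        )
    return w


def effective_charge_from_energy(dF_elec: float, phi_m: float) -> float:
    """Measured effective charge q_m = dF_elec / phi_m (e).

    A positive trap depth in a negative midplane potential yields the
    signed negative charge of the molecule.
    """
    if phi_m == 0.0:
        raise InvalidInputError(
            "phi_m = 0: effective charge undefined (no electrostatic trap)"
        )
    return dF_elec / phi_m


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------


def _step_profile(rho, w_depth, l_s, w_b):
    """Radial free energy F(rho) = -W * S(rho), smooth step at the rim."""
    u = 4.0 * (rho - (l_s - 0.5 * w_b)) / w_b
    return -w_depth * 0.5 * (1.0 - np.tanh(u))


def _radial_force(rho, w_depth, l_s, w_b):
    """-dF/drho for the smooth-step landscape (k_B T / nm)."""
    u = 4.0 * (rho - (l_s - 0.5 * w_b)) / w_b
    sech2 = 1.0 / np.cosh(u) ** 2
    return -w_depth * 2.0 / w_b * sech2


def _bd_loop_numpy(n_walkers, d_coef, dt, w_depth, l_s, w_b, rho_abs, seed, max_steps):
    rng = np.random.default_rng(seed)
    sig = math.sqrt(2.0 * d_coef * dt)
    x = np.zeros(n_walkers)
    y = np.zeros(n_walkers)
    t_out = np.full(n_walkers, np.nan)
    alive = np.arange(n_walkers)
    for step in range(1, max_steps + 1):
        rho = np.hypot(x, y)
        f = _radial_force(np.maximum(rho, 1e-12), w_depth, l_s, w_b)
        scale = d_coef * dt * f / np.maximum(rho, 1e-12)
        x = x + scale * x + sig * rng.standard_normal(alive.size)
        y = y + scale * y + sig * rng.standard_normal(alive.size)
        out = np.hypot(x, y) >= rho_abs
        if out.any():
            t_out[alive[out]] = step * dt
            keep = ~out
            x, y, alive = x[keep], y[keep], alive[keep]
            if alive.size == 0:
                break
    return t_out


try:  # optional numba acceleration of the walker loop
    import numba as _nb

    @_nb.njit(cache=True, fastmath=True)
    def _bd_loop_numba(n_walkers, d_coef, dt, w_depth, l_s, w_b, rho_abs, seed, max_steps):  # pragma: no cover
        np.random.seed(seed)
        sig = math.sqrt(2.0 * d_coef * dt)
        t_out = np.full(n_walkers, np.nan)
        rho_c = l_s - 0.5 * w_b
        abs2 = rho_abs * rho_abs
        # drift-per-unit-coordinate D dt f(rho)/rho tabulated against rho^2
        # (dense enough that linear interpolation is exact to float noise)
        ntab = 16384
        dr2 = abs2 / (ntab - 1)
        tab = np.empty(ntab)
        for k in range(ntab):
            rho = math.sqrt(k * dr2)
            r_safe = rho if rho > 1.0 else 1.0  # rim force is negligible there
            u = 4.0 * (r_safe - rho_c) / w_b
            ch = math.cosh(u)
            force = -w_depth * 2.0 / w_b / (ch * ch)
            tab[k] = d_coef * dt * force / r_safe
        inv_dr2 = 1.0 / dr2
        nbuf = 16384
        buf = np.random.standard_normal(nbuf)
        ib = 0
        for w in range(n_walkers):
            x = 0.0
            y = 0.0
            for step in range(1, max_steps + 1):
                r2 = x * x + y * y
                if r2 >= abs2:
                    t_out[w] = (step - 1) * dt
                    break
                pos = r2 * inv_dr2
                k = int(pos)
                frac = pos - k
                scale = tab[k] + frac * (tab[k + 1] - tab[k])
                if ib >= nbuf - 1:
                    buf = np.random.standard_normal(nbuf)
                    ib = 0
                x += scale * x + sig * buf[ib]
                y += scale * y + sig * buf[ib + 1]
                ib += 2
        return t_out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def simulate_escape_bd(
    device: SlitDevice,
    well: WellDepth,
    params: BDParams,
    w_b: float = 8.7,
    rho_abs: float | None = None,
    max_steps: int = 200_000_000,
    backend: str = "auto",
) -> ResidenceTimeSet:
    """First-passage times of overdamped walkers out of a radial step well.

    Walkers start on the pocket axis in the landscape
    F(rho) = -W * S(rho), with S a smooth step from 1 inside the pocket
    to 0 outside over a rim of width ``w_b`` (nm), and are absorbed at
    ``rho_abs`` (default 1.2 * pocket radius). Identical seeds give
    identical event lists for a given backend.
    """
    if params.dt <= 0 or math.sqrt(2.0 * params.D * params.dt) >= device.l_s / 50.0:
        raise InvalidTimestepError(
            "timestep too large: sqrt(2 D dt) must stay below l_s / 50"
        )
    if rho_abs is None:
        rho_abs = 1.2 * device.l_s
    if rho_abs <= device.l_s:
        raise InvalidInputError("absorbing radius must exceed the pocket radius")
    use_numba = _HAVE_NUMBA and backend in ("auto", "numba")
    if backend == "numba" and not _HAVE_NUMBA:
        raise InvalidInputError("numba backend requested but numba is unavailable")
    loop = _bd_loop_numba if use_numba else _bd_loop_numpy
    times = loop(
        params.n_walkers,
        params.D,
        params.dt,
        well.W,
        device.l_s,
        w_b,
        rho_abs,
        params.seed,
        max_steps,
    )
    if np.isnan(times).any():
        raise DegenerateDataError(
            f"{int(np.isnan(times).sum())} walkers did not escape within max_steps"
        )
    return ResidenceTimeSet(durations=times, t_min=0.0, t_cycle=params.dt, seed=params.seed)


def mean_first_passage_quadrature(
    device: SlitDevice,
    w_depth: float,
    d_coef: float,
    w_b: float = 8.7,
    rho_abs: float | None = None,
    n_grid: int = 20001,
) -> float:
    """Independent 1D oracle for the radial mean first-passage time.

    T(0 -> rho_abs) = (1/D) int_0^abs dy e^{F(y)}/y int_0^y x e^{-F(x)} dx
    for isotropic 2D diffusion in the radial potential F (k_B T).
    Reduces to rho_abs^2 / (4 D) for W = 0.
    """
    if rho_abs is None:
        rho_abs = 1.2 * device.l_s
    rho = np.linspace(0.0, rho_abs, n_grid)
    f_pot = _step_profile(rho, w_depth, device.l_s, w_b)
    inner = cumulative_trapezoid(rho * np.exp(-f_pot), rho, initial=0.0)
    integrand = np.zeros_like(rho)
    integrand[1:] = np.exp(f_pot[1:]) / rho[1:] * inner[1:]
    # as rho -> 0 the integrand -> rho/2 * e^{F-F} -> 0
    return float(trapezoid(integrand, rho) / d_coef)


class PrefactorMap:
    """Interpolable ln(t_esc) vs W relation from BD calibration runs."""

    def __init__(self, w_values, t_esc_values, se_values, seed):
        order = np.argsort(w_values)
        self.w_values = np.asarray(w_values, dtype=float)[order]
        self.t_esc_values = np.asarray(t_esc_values, dtype=float)[order]
        self.se_values = np.asarray(se_values, dtype=float)[order]
        self.seed = seed
        self._ln_t = np.log(self.t_esc_values)

    def t_esc(self, w):
        """Interpolated mean escape time (ms) at well depth w (k_B T)."""
        return float(np.exp(np.interp(w, self.w_values, self._ln_t)))

    def well_depth(self, t_esc):
        """Invert the calibration: W at a measured escape time."""
        return float(np.interp(math.log(t_esc), self._ln_t, self.w_values))

    def t0(self, w):
        """Effective Kramers prefactor t_0(W) = t_esc(W) e^{-W} (ms)."""
        return self.t_esc(w) * math.exp(-w)

    def slope(self):
        """Least-squares slope of ln t_esc vs W (unit in the deep-well limit)."""
        return float(np.polyfit(self.w_values, self._ln_t, 1)[0])


def calibrate_prefactor(
    device: SlitDevice,
    params: BDParams,
    w_list,
    w_b: float = 8.7,
    rho_abs: float | None = None,
    backend: str = "auto",
    n_walkers_list=None,
) -> PrefactorMap:
    """BD-based t_esc(W) lookup over the working range of well depths.

    Monotone in W; approximately unit slope of ln t_esc vs W for deep
    wells. Re-running with the same seed reproduces the table exactly.
    ``n_walkers_list`` optionally sets a per-depth walker budget (deep
    wells cost exp(W) steps per walker).
    """
    w_list = np.asarray(sorted(w_list), dtype=float)
    if len(w_list) < 2:
        raise InvalidInputError("need at least two well depths to calibrate")
    if n_walkers_list is None:
        n_walkers_list = [params.n_walkers] * len(w_list)
    if len(n_walkers_list) != len(w_list):
        raise InvalidInputError("n_walkers_list must match w_list in length")
    t_means, t_ses = [], []
    for k, w in enumerate(w_list):
        p = BDParams(
            r_H=params.r_H,
            dt=params.dt,
            seed=params.seed + 1000 * k,
            n_walkers=int(n_walkers_list[k]),
        )
        ev = simulate_escape_bd(
            device, WellDepth(W=w, dF_elec=w), p, w_b=w_b, rho_abs=rho_abs, backend=backend
        )
        t_means.append(ev.durations.mean())
        t_ses.append(ev.durations.std(ddof=1) / math.sqrt(ev.N))
    return PrefactorMap(w_list, t_means, t_ses, params.seed)
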