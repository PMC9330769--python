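"""Forward model for complete synthetic experiments.

Generates effective-charge measurement tables, censored residence-time
event tables and two-level intensity traces from an assumed molecular
geometry and apparatus description, so that every pipeline stage can be
exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .electrolyte import ElectrolyteConditions, SlitDevice, midplane_potential
from .errors import (
    DependencyError,
    InvalidFixtureError,
    InvalidInputError,
    UnphysicalConfigurationError,
)
from .inference import MeasuredCharge
from .kinetics import ResidenceTimeSet

__all__ = ["ExperimentTruth", "generate_measurements", "generate_events", "generate_trace"]

#: Camera cycle time (ms) by fragment length, mirroring typical imaging rates.
DEFAULT_T_CYCLE = {30: 20.0, 40: 30.0, 60: 50.0}


@dataclass
class ExperimentTruth:
    """Ground truth for one synthetic experiment.

    ``geometry`` maps species label to its true (rise, radius) in
    Angstrom; ``salts`` maps salt label to (f_phi, f_ion,
    ElectrolyteConditions).
    """

    geometry: dict
    salts: dict
    f_A: float = -0.5
    device: SlitDevice = field(
        default_factory=lambda: SlitDevice(h=30.0, l_s=250.0, d=150.0, phi_s=-2.8)
    )
    lengths: tuple = (30, 40, 60)
    noise_frac: float = 0.003
    N_events: int = 10_000
    t_0: float = 1.0  # ms
    t_cycle: dict = field(default_factory=lambda: dict(DEFAULT_T_CYCLE))
    seed: int = 0

    def __post_init__(self):
        if self.N_events < 100:
            raise InvalidInputError("N_events must be >= 100")
        if self.noise_frac < 0 or self.t_0 <= 0:
            raise InvalidInputError("noise_frac must be >= 0 and t_0 > 0")
        for f_phi, f_ion, _ in self.salts.values():
            if f_phi * f_ion <= 0:
                raise InvalidInputError("f_M = f_phi * f_ion must be positive")

    def f_M(self, salt: str) -> float:
        f_phi, f_ion, _ = self.salts[salt]
        return f_phi * f_ion

    def conditions(self, salt: str) -> ElectrolyteConditions:
        return self.salts[salt][2]


def generate_measurements(truth: ExperimentTruth, surfaces: dict) -> list:
    """Draw noisy measured charges q_m ~ N(f_M q_eff + f_A, sigma).

    ``surfaces`` maps (salt, n_bp) to the corresponding effective-charge
    surface. Reproducible under ``truth.seed``; with ``noise_frac = 0``
    the deterministic measurement model is returned exactly.
    """
    rng = np.random.default_rng(truth.seed)
    out = []
    for salt in truth.salts:
        for species, (b, r) in truth.geometry.items():
            for n in truth.lengths:
                key = (salt, n)
                if key not in surfaces:
                    raise DependencyError(
                        f"missing effective-charge surface for salt={salt}, n_bp={n}"
                    )
                q_eff = float(surfaces[key].q_eff_at(b, r))
                mean = truth.f_M(salt) * q_eff + truth.f_A
                sigma = truth.noise_frac * abs(mean)
                q_m = mean + sigma * rng.standard_normal() if sigma > 0 else mean
                out.append(
                    MeasuredCharge(
                        species=species,
                        n_bp=n,
                        q_m=q_m,
                        sigma=sigma if sigma > 0 else 1e-12,
                        salt=salt,
                    )
                )
    return out


def generate_events(
    truth: ExperimentTruth,
    measurement: MeasuredCharge,
    censor: bool = True,
    discretize: bool = True,
    seed_offset: int = 0,
) -> ResidenceTimeSet:
    """Censored exponential residence times implied by one measured charge.

    The trap depth is W = q_m * phi_m (both negative, so W > 0), the mean
    escape time t_esc = t_0 exp(W). Durations are rounded to whole camera
    cycles; events shorter than half a cycle vanish (censoring), so the
    detection floor is t_cycle / 2.
    """
    cond = truth.conditions(measurement.salt)
    phi_m = midplane_potential(truth.device, cond)
    w_depth = measurement.q_m * phi_m
    if w_depth <= 0:
        raise UnphysicalConfigurationError(
            f"W = q_m * phi_m = {w_depth:.3g} <= 0: no trapping"
        )
    t_esc = truth.t_0 * math.exp(w_depth)
    t_cycle = truth.t_cycle.get(measurement.n_bp, 30.0)
    rng = np.random.default_rng(
        truth.seed + 7919 * measurement.n_bp + seed_offset
    )
    dt = rng.exponential(t_esc, size=truth.N_events)
    if discretize:
        frames = np.round(dt / t_cycle).astype(np.int64)
        if censor:
            frames = frames[frames >= 1]
        else:
            frames = np.maximum(frames, 1)
        dt = frames * t_cycle
        t_min = 0.5 * t_cycle
    else:
        if censor:
            dt = dt[dt >= t_cycle]
            t_min = t_cycle
        else:
            t_min = 0.0
    return ResidenceTimeSet(
        durations=dt, t_min=t_min, t_cycle=t_cycle, seed=truth.seed + seed_offset
    )


def generate_trace(
    events: ResidenceTimeSet,
    snr: float,
    seed: int,
    gap_frames: int = 10,
    starts: np.ndarray | None = None,
):
    """Two-level telegraph intensity trace embedding the given events.

    Events are placed sequentially with ``gap_frames`` empty frames
    between them (or at explicit non-overlapping ``starts`` in frame
    units). Background level 0, signal level 1, Gaussian noise of
    standard deviation 1/snr. A midpoint threshold recovers the event
    durations exactly for snr >= 10.
    """
    if snr <= 0:
        raise InvalidInputError("snr must be positive")
    frames = np.maximum(np.round(events.durations / events.t_cycle), 1).astype(np.int64)
    if starts is None:
        starts = np.empty(len(frames), dtype=np.int64)
        pos = gap_frames
        for i, f in enumerate(frames):
            starts[i] = pos
            pos += f + gap_frames
        n_total = pos
    else:
        starts = np.asarray(starts, dtype=np.int64)
        if len(starts) != len(frames):
            raise InvalidFixtureError("starts must match the number of events")
        order = np.argsort(starts)
        s, f = starts[order], frames[order]
        if np.any(s[1:] < s[:-1] + f[:-1]) or (len(s) and s[0] < 1):
            raise InvalidFixtureError("events overlap or touch the trace boundary")
        n_total = int((s[-1] + f[-1]) + gap_frames) if len(s) else 2 * gap_frames
    trace = np.zeros(max(int(n_total), 2 * gap_frames))
    for s, f in zip(starts, frames):
        trace[s : s + f] = 1.0
    rng = np.random.default_rng(seed)
    trace = trace + rng.standard_normal(trace.size) / snr
    return trace
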