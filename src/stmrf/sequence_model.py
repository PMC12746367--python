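"""Domain types for saturation-transfer MRF acquisition schedules.

A schedule is an ordered list of per-image saturation events (power B1[n],
frequency offset Δω[n], pulse-train timing) plus global readout parameters.
These types carry the acquisition-parameter matrix that the CRB-guided
optimizer searches over, together with the timing arithmetic and the
box bounds of the scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import yaml

#: Gyromagnetic ratio of ¹H in rad s⁻¹ T⁻¹.
GAMMA_H = 2.675e8

#: Timing slack (s) allowed when checking pulse-train fit inside t_sat.
TIMING_TOL = 1e-9

SCHEDULE_FORMAT = "stmrf-schedule"
SCHEDULE_VERSION = 1


def ppm_to_rad(ppm: float, b0: float, gamma: float = GAMMA_H) -> float:
    """Chemical-shift/offset conversion: ppm → rad s⁻¹ at field ``b0`` (T)."""
    return ppm * 1e-6 * gamma * b0


def rad_to_ppm(omega: float, b0: float, gamma: float = GAMMA_H) -> float:
    return omega / (1e-6 * gamma * b0)


def ut_to_rad(b1_ut: float, gamma: float = GAMMA_H) -> float:
    """Saturation amplitude conversion: µT → nutation rate ω1 in rad s⁻¹."""
    return b1_ut * 1e-6 * gamma


class Lineshape(str, Enum):
    """How a pool's RF absorption is modelled.

    ``FULL_BM_LORENTZIAN``: pool carries full (Mx, My, Mz) Bloch-McConnell
    dynamics; its T2 yields a Lorentzian absorption implicitly.
    ``SUPERLORENTZIAN_RATE``: Mz-only semisolid pool saturated at the rate
    W = π·ω1²·g(Δ) with a super-Lorentzian absorption lineshape g.
    """

    FULL_BM_LORENTZIAN = "full_bm_lorentzian"
    SUPERLORENTZIAN_RATE = "superlorentzian_rate"


@dataclass(frozen=True)
class Pool:
    """One proton pool: relaxation, size, exchange and chemical shift.

    Parameters
    ----------
    t1, t2 : float
        Longitudinal / transverse relaxation times in seconds.
    f : float
        Proton volume fraction relative to water (water itself has f=1).
    k : float
        Exchange rate toward water, s⁻¹ (0 for the water pool).
    delta : float
        Chemical shift in ppm relative to water.
    """

    name: str
    t1: float
    t2: float
    f: float = 1.0
    k: float = 0.0
    delta: float = 0.0
    lineshape: Lineshape = Lineshape.FULL_BM_LORENTZIAN

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"pool {self.name!r}: relaxation times must be > 0")
        if self.k < 0:
            raise ValueError(f"pool {self.name!r}: exchange rate must be >= 0")
        if not 0 < self.f <= 1:
            raise ValueError(f"pool {self.name!r}: volume fraction must be in (0, 1]")


@dataclass(frozen=True)
class PoolSystem:
    """Water plus exchanging solute / semisolid pools at a given field."""

    water: Pool
    solutes: tuple[Pool, ...]
    b0: float
    gamma: float = GAMMA_H

    def __post_init__(self) -> None:
        object.__setattr__(self, "solutes", tuple(self.solutes))
        for p in self.solutes:
            if p.k == 0:
                raise ValueError(f"non-water pool {p.name!r} must have k > 0")
            if not p.f < 1:
                raise ValueError(f"non-water pool {p.name!r} must have f < 1")

    def with_solute_params(self, fs: float, ksw: float, index: int = 0) -> "PoolSystem":
        """Return a copy with solute ``index`` given fraction ``fs`` and rate ``ksw``."""
        solutes = list(self.solutes)
        solutes[index] = replace(solutes[index], f=fs, k=ksw)
        return replace(self, solutes=tuple(solutes))


class PulseShape(str, Enum):
    RECT = "rect"
    SPIN_LOCK = "spin_lock"


@dataclass(frozen=True)
class SaturationEvent:
    """One image's saturation block.

    A continuous-wave block is ``pulse_count=1, duty_cycle=1,
    pulse_duration=t_sat``.  A pulsed train repeats ``pulse_count`` cycles of
    an RF-on segment of ``pulse_duration`` followed by a gap of
    ``pulse_duration·(1−duty)/duty``; any remaining time up to ``t_sat`` is
    RF-free.
    """

    b1: float  # µT
    offset: float  # ppm
    t_sat: float  # s
    pulse_count: int = 1
    pulse_duration: float | None = None
    duty_cycle: float = 1.0
    shape: PulseShape = PulseShape.RECT

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        if self.t_sat < 0:
            raise ValueError("t_sat must be >= 0")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be >= 1")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must be in (0, 1]")
        if self.pulse_duration is None:
            object.__setattr__(self, "pulse_duration", self.t_sat)
        train = self.pulse_count * self.pulse_duration / self.duty_cycle
        if train > self.t_sat + TIMING_TOL:
            raise ValueError(
                f"pulse train ({train:.6g} s) does not fit in t_sat ({self.t_sat:.6g} s)"
            )

    @property
    def gap_duration(self) -> float:
        """RF-free time after each pulse within a train cycle, s."""
        return self.pulse_duration * (1.0 - self.duty_cycle) / self.duty_cycle


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered saturation events plus global recovery/readout parameters."""

    events: tuple[SaturationEvent, ...]
    t_rec: float  # s, recovery before each readout
    flip_angle: float  # degrees
    spoil_transverse: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.t_rec < 0:
            raise ValueError("t_rec must be >= 0")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def b1_values(self) -> np.ndarray:
        """Saturation power vector B1[n] in µT."""
        return np.array([e.b1 for e in self.events], dtype=float)

    @property
    def offset_values(self) -> np.ndarray:
        """Frequency offset vector Δω[n] in ppm."""
        return np.array([e.offset for e in self.events], dtype=float)

    def with_values(
        self,
        b1: Sequence[float] | None = None,
        offsets: Sequence[float] | None = None,
    ) -> "AcquisitionSchedule":
        """Copy with B1 and/or offsets replaced (timing untouched)."""
        b1_arr = self.b1_values if b1 is None else np.asarray(b1, dtype=float)
        off_arr = self.offset_values if offsets is None else np.asarray(offsets, dtype=float)
        if len(b1_arr) != len(self.events) or len(off_arr) != len(self.events):
            raise ValueError("replacement vectors must match the schedule length")
        events = tuple(
            replace(e, b1=float(b), offset=float(o))
            for e, b, o in zip(self.events, b1_arr, off_arr)
        )
        return replace(self, events=events)


@dataclass(frozen=True)
class ScheduleBounds:
    """Scanner box constraints for the optimizer."""

    b1_min: float
    b1_max: float
    offset_min: float | None = None
    offset_max: float | None = None
    offset_fixed: float | None = None
    optimize_offsets: bool = False

    def __post_init__(self) -> None:
        if self.b1_min < 0:
            raise ValueError("b1_min must be >= 0")
        if self.b1_max <= self.b1_min:
            raise ValueError("b1_max must exceed b1_min")
        if self.offset_fixed is not None and self.optimize_offsets:
            raise ValueError("offset_fixed is incompatible with optimize_offsets")
        if self.optimize_offsets and (self.offset_min is None or self.offset_max is None):
            raise ValueError("optimize_offsets requires offset_min and offset_max")


def schedule_duration(schedule: AcquisitionSchedule) -> float:
    """Total acquisition time in seconds: Σ (t_sat + t_rec) over events.

    The readout itself is treated as instantaneous, so a continuous-wave
    protocol of N images lasts exactly N·(Tsat + Trec).
    """
    return float(sum(e.t_sat + schedule.t_rec for e in schedule.events))


def flatten_schedule(
    schedule: AcquisitionSchedule, bounds: ScheduleBounds
) -> tuple[np.ndarray, Callable[[np.ndarray], AcquisitionSchedule]]:
    """Map a schedule to the optimizer's flat vector and back.

    Returns ``(x, unflatten)`` where ``x`` is ``B1[n]`` (µT) optionally
    followed by ``Δω[n]`` (ppm) when offsets are free, and
    ``unflatten(x)`` rebuilds a schedule with the same timing.
    """
    n = len(schedule)
    if bounds.optimize_offsets:
        x = np.concatenate([schedule.b1_values, schedule.offset_values])
    else:
        x = schedule.b1_values

    def unflatten(vec: np.ndarray) -> AcquisitionSchedule:
        vec = np.asarray(vec, dtype=float)
        if bounds.optimize_offsets:
            if vec.size != 2 * n:
                raise ValueError(f"expected vector of length {2 * n}, got {vec.size}")
            return schedule.with_values(b1=vec[:n], offsets=vec[n:])
        if vec.size != n:
            raise ValueError(f"expected vector of length {n}, got {vec.size}")
        return schedule.with_values(b1=vec)

    return x, unflatten


def bound_pairs(bounds: ScheduleBounds, n: int) -> list[tuple[float, float]]:
    """Per-component (lo, hi) pairs matching the flattened vector layout."""
    pairs = [(bounds.b1_min, bounds.b1_max)] * n
    if bounds.optimize_offsets:
        pairs += [(bounds.offset_min, bounds.offset_max)] * n
    return pairs


# ---------------------------------------------------------------------------
# serialization

def schedule_to_dict(schedule: AcquisitionSchedule) -> dict:
    return {
        "format": SCHEDULE_FORMAT,
        "version": SCHEDULE_VERSION,
        "t_rec_s": float(schedule.t_rec),
        "flip_angle_deg": float(schedule.flip_angle),
        "spoil_transverse": bool(schedule.spoil_transverse),
        "events": [
            {
                "b1_uT": float(e.b1),
                "offset_ppm": float(e.offset),
                "t_sat_s": float(e.t_sat),
                "pulse_count": int(e.pulse_count),
                "pulse_duration_s": float(e.pulse_duration),
                "duty_cycle": float(e.duty_cycle),
                "shape": e.shape.value,
            }
            for e in schedule.events
        ],
    }


def schedule_from_dict(doc: dict) -> AcquisitionSchedule:
    if doc.get("format") != SCHEDULE_FORMAT:
        raise ValueError("not a schedule document")
    if doc.get("version") != SCHEDULE_VERSION:
        raise ValueError(f"unsupported schedule version {doc.get('version')!r}")
    events = tuple(
        SaturationEvent(
            b1=e["b1_uT"],
            offset=e["offset_ppm"],
            t_sat=e["t_sat_s"],
            pulse_count=e["pulse_count"],
            pulse_duration=e["pulse_duration_s"],
            duty_cycle=e["duty_cycle"],
            shape=PulseShape(e["shape"]),
        )
        for e in doc["events"]
    )
    return AcquisitionSchedule(
        events=events,
        t_rec=doc["t_rec_s"],
        flip_angle=doc["flip_angle_deg"],
        spoil_transverse=doc["spoil_transverse"],
    )


def save_schedule(schedule: AcquisitionSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=True)


def load_schedule(path) -> AcquisitionSchedule:
    with open(path) as fh:
        return schedule_from_dict(yaml.safe_load(fh))


def flip_angle_rad(schedule: AcquisitionSchedule) -> float:
    return math.radians(schedule.flip_angle)
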