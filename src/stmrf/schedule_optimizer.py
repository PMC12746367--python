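"""Schedule search: SQP local minimization wrapped in basin hopping.

The acquisition parameters (saturation powers B1[n], optionally the
frequency offsets Δω[n]) are minimized against the dictionary-wide CRB
trace loss.  Sequential quadratic programming (SLSQP with forward
finite-difference gradients) performs the local descent; an outer
basin-hopping loop applies seeded random perturbations with Metropolis
acceptance to escape local minima, and every candidate is recorded in a
replayable trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .crb_engine import CRBConfig, UnidentifiableNodeError, crb_loss
from .dictionary_engine import Dictionary
from .sequence_model import (
    AcquisitionSchedule,
    SaturationEvent,
    ScheduleBounds,
    bound_pairs,
    flatten_schedule,
)

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "random_initial_schedule",
    "sqp_minimize",
    "basin_hop_minimize",
    "basin_hopping_optimize",
]


@dataclass(frozen=True)
class OptimizerConfig:
    n_hops: int = 20
    hop_stepsize: float = 0.25  # fraction of each bound range
    temperature: float = 1.0  # Metropolis scale, loss units
    sqp_max_iter: int = 100
    sqp_ftol: float = 1e-6
    # forward-difference step for the SQP gradient, in the optimizer's
    # [0, 1]-scaled coordinates; must sit above the simulated objective's
    # numerical noise floor
    sqp_fd_step: float = 1e-4
    seed: int = 0
    n_restarts: int = 4
    max_retries: int = 3

    def __post_init__(self) -> None:
        if self.n_hops < 0:
            raise ValueError("n_hops must be >= 0")
        if not 0 < self.hop_stepsize <= 1:
            raise ValueError("hop_stepsize must be in (0, 1]")


@dataclass
class TraceEntry:
    loss: float
    x: np.ndarray
    accepted: bool
    clipped: bool = False


@dataclass
class OptimizationTrace:
    entries: list[TraceEntry] = field(default_factory=list)
    initial_x: np.ndarray | None = None
    initial_loss: float = math.inf
    best_x: np.ndarray | None = None
    best_loss: float = math.inf
    best_schedule: AcquisitionSchedule | None = None
    initial_schedule: AcquisitionSchedule | None = None

    def record(self, loss: float, x: np.ndarray, accepted: bool, clipped: bool = False) -> None:
        self.entries.append(TraceEntry(loss=loss, x=np.array(x), accepted=accepted, clipped=clipped))

    def to_dict(self) -> dict:
        return {
            "initial_loss": self.initial_loss,
            "best_loss": self.best_loss,
            "initial_x": None if self.initial_x is None else self.initial_x.tolist(),
            "best_x": None if self.best_x is None else self.best_x.tolist(),
            "entries": [
                {
                    "loss": e.loss,
                    "x": e.x.tolist(),
                    "accepted": e.accepted,
                    "clipped": e.clipped,
                }
                for e in self.entries
            ],
        }


def random_initial_schedule(
    bounds: ScheduleBounds,
    n: int,
    seed: int | np.random.Generator,
    base_event: SaturationEvent,
    t_rec: float,
    flip_angle: float,
    spoil_transverse: bool = True,
) -> AcquisitionSchedule:
    """Uniformly random starting schedule within the scanner bounds.

    Powers are drawn from U(b1_min, b1_max); offsets are the fixed value
    when the protocol pins them, otherwise U(offset_min, offset_max).
    Timing (pulse train, recovery, flip angle) comes from ``base_event``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b1 = rng.uniform(bounds.b1_min, bounds.b1_max, size=n)
    if bounds.offset_fixed is not None:
        offsets = np.full(n, bounds.offset_fixed)
    elif bounds.optimize_offsets:
        offsets = rng.uniform(bounds.offset_min, bounds.offset_max, size=n)
    else:
        offsets = np.full(n, base_event.offset)
    events = tuple(
        SaturationEvent(
            b1=float(b),
            offset=float(o),
            t_sat=base_event.t_sat,
            pulse_count=base_event.pulse_count,
            pulse_duration=base_event.pulse_duration,
            duty_cycle=base_event.duty_cycle,
            shape=base_event.shape,
        )
        for b, o in zip(b1, offsets)
    )
    return AcquisitionSchedule(
        events=events, t_rec=t_rec, flip_angle=flip_angle, spoil_transverse=spoil_transverse
    )


def sqp_minimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    max_iter: int = 100,
    ftol: float = 1e-6,
    fd_step: float = 1.5e-8,
) -> tuple[np.ndarray, float, int]:
    """Bound-constrained SQP local step (SLSQP, forward-difference gradients).

    Returns ``(x*, f*, iterations)`` with x* clipped into the box to
    machine tolerance.  The returned pair is never worse than the start:
    if the line search ends above f(x0), x0 is returned.
    """
    x0 = np.asarray(x0, float)
    f0 = float(objective(x0))
    if not math.isfinite(f0):
        raise ValueError(f"objective not finite at x0={x0}")
    res = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": ftol, "eps": fd_step},
    )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x = np.clip(res.x, lo, hi)
    f = float(res.fun)
    if not math.isfinite(f) or f > f0:
        return x0, f0, int(res.nit)
    return x, f, int(res.nit)


def basin_hop_minimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    config: OptimizerConfig | None = None,
    rng: np.random.Generator | None = None,
    trace: OptimizationTrace | None = None,
) -> OptimizationTrace:
    """Basin hopping on a plain objective over a box.

    Each hop perturbs the accepted point uniformly within
    ``hop_stepsize × range`` per coordinate, clips to the box, runs the
    SQP local step, and applies Metropolis acceptance at the configured
    temperature.  The best point ever seen is returned; it is never worse
    than f(x0) because the initial point participates.
    """
    if config is None:
        config = OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if trace is None:
        trace = OptimizationTrace()

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo

    x0 = np.asarray(x0, float)
    f0 = float(objective(x0))
    trace.initial_x = x0.copy()
    trace.initial_loss = f0
    trace.best_x, trace.best_loss = x0.copy(), f0

    x_loc, f_loc, _ = sqp_minimize(
        objective, x0, bounds, config.sqp_max_iter, config.sqp_ftol, config.sqp_fd_step
    )
    trace.record(f_loc, x_loc, accepted=True)
    if f_loc < trace.best_loss:
        trace.best_x, trace.best_loss = x_loc.copy(), f_loc
    x_acc, f_acc = x_loc, f_loc

    for _ in range(config.n_hops):
        for attempt in range(config.max_retries + 1):
            step = rng.uniform(-1.0, 1.0, size=x_acc.size) * config.hop_stepsize * span
            x_trial = x_acc + step
            clipped = bool(np.any(x_trial < lo) or np.any(x_trial > hi))
            x_trial = np.clip(x_trial, lo, hi)
            try:
                x_new, f_new, _ = sqp_minimize(
                    objective, x_trial, bounds, config.sqp_max_iter,
                    config.sqp_ftol, config.sqp_fd_step,
                )
                break
            except (ValueError, FloatingPointError, RuntimeError):
                if attempt == config.max_retries:
                    raise
        if f_new < trace.best_loss:
            trace.best_x, trace.best_loss = x_new.copy(), f_new
        # Metropolis: accept improvements, and uphill moves with
        # probability exp(-Δ/T); ties keep the earlier point
        delta = f_new - f_acc
        accept = delta < 0 or (
            config.temperature > 0 and rng.random() < math.exp(-delta / config.temperature)
        )
        trace.record(f_new, x_new, accepted=accept, clipped=clipped)
        if accept:
            x_acc, f_acc = x_new, f_new
    return trace


def basin_hopping_optimize(
    dict_factory: Callable[[AcquisitionSchedule], Dictionary],
    crb_config: CRBConfig,
    bounds: ScheduleBounds,
    opt_config: OptimizerConfig,
    initial_schedule: AcquisitionSchedule,
) -> OptimizationTrace:
    """Minimize the dictionary-wide CRB trace loss over the schedule.

    ``dict_factory`` regenerates the dictionary de novo for every candidate
    schedule.  Powers (µT) and offsets (ppm) are rescaled to [0, 1]
    internally for conditioning; the trace and the returned schedule are in
    physical units.
    """
    x_phys0, unflatten = flatten_schedule(initial_schedule, bounds)
    pairs = bound_pairs(bounds, len(initial_schedule))
    lo = np.array([p[0] for p in pairs])
    hi = np.array([p[1] for p in pairs])
    span = hi - lo

    def to_phys(u: np.ndarray) -> np.ndarray:
        return lo + np.asarray(u, float) * span

    #: finite stand-in loss for candidates whose dictionary has an
    #: unidentifiable node (e.g. all powers near zero); keeps the SQP line
    #: search alive so it can back away instead of aborting the run
    UNIDENTIFIABLE_PENALTY = 1e20

    def objective(u: np.ndarray) -> float:
        schedule = unflatten(to_phys(u))
        try:
            return crb_loss(dict_factory(schedule), crb_config).loss
        except UnidentifiableNodeError:
            return UNIDENTIFIABLE_PENALTY

    u0 = (x_phys0 - lo) / span
    rng = np.random.default_rng(opt_config.seed)
    unit_bounds = [(0.0, 1.0)] * len(u0)
    trace = basin_hop_minimize(objective, u0, unit_bounds, opt_config, rng)

    # rewrite the trace in physical units
    trace.initial_x = to_phys(trace.initial_x)
    trace.best_x = to_phys(trace.best_x)
    for e in trace.entries:
        e.x = to_phys(e.x)
    trace.initial_schedule = initial_schedule
    trace.best_schedule = unflatten(trace.best_x)
    return trace
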