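"""Synthetic-signal dictionary over the (fs, ksw) parameter grid.

Block 1 of the acquisition-optimization pipeline: for every node of the
exchange-parameter grid the Bloch–McConnell simulator produces the signal
trajectory of the candidate schedule.  The dictionary is regenerated from
scratch for every candidate schedule the optimizer evaluates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .bm_simulator import IsochromatEnsemble, simulate_schedule
from .sequence_model import AcquisitionSchedule, PoolSystem


@dataclass(frozen=True)
class ParameterGrid:
    """Strictly increasing (fs, ksw) axes; row-major node order, fs outer."""

    fs_values: np.ndarray
    ksw_values: np.ndarray
    fs_spacing: str = "linear"
    ksw_spacing: str = "linear"

    def __post_init__(self) -> None:
        fs = np.asarray(self.fs_values, float)
        ksw = np.asarray(self.ksw_values, float)
        object.__setattr__(self, "fs_values", fs)
        object.__setattr__(self, "ksw_values", ksw)
        for name, ax in (("fs", fs), ("ksw", ksw)):
            if ax.size < 3:
                raise ValueError(f"{name} axis needs at least 3 values")
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fs_values.size, self.ksw_values.size

    @property
    def n_nodes(self) -> int:
        return self.fs_values.size * self.ksw_values.size

    def node_index(self, i_fs: int, i_ksw: int) -> int:
        return i_fs * self.ksw_values.size + i_ksw

    def node_coords(self, index: int) -> tuple[int, int]:
        n_ksw = self.ksw_values.size
        if not 0 <= index < self.n_nodes:
            raise IndexError(f"node index {index} out of range")
        return index // n_ksw, index % n_ksw

    def node_theta(self, index: int) -> tuple[float, float]:
        i, j = self.node_coords(index)
        return float(self.fs_values[i]), float(self.ksw_values[j])

    def interior_indices(self) -> np.ndarray:
        nf, nk = self.shape
        idx = [
            self.node_index(i, j)
            for i in range(1, nf - 1)
            for j in range(1, nk - 1)
        ]
        return np.array(idx, dtype=int)


@dataclass(frozen=True)
class Dictionary:
    """Simulated trajectories, one row per (fs, ksw) node."""

    grid: ParameterGrid
    signals: np.ndarray  # (n_nodes, N)
    schedule: AcquisitionSchedule
    norms: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, float)
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "norms", np.asarray(self.norms, float))
        if sig.shape[0] != self.grid.n_nodes:
            raise ValueError("row count must equal the number of grid nodes")
        if np.any(self.norms <= 0):
            raise ValueError("every dictionary row must have positive norm")


def generate_dictionary(
    pools: PoolSystem,
    grid: ParameterGrid,
    schedule: AcquisitionSchedule,
    ensemble: IsochromatEnsemble | None = None,
    solute_index: int = 0,
    n_jobs: int = 1,
) -> Dictionary:
    """Simulate every grid node's trajectory (row-major: fs outer, ksw inner).

    Parallel generation is permitted; row order and values are independent
    of the worker count because every node is simulated independently and
    deterministically.
    """
    thetas = [grid.node_theta(r) for r in range(grid.n_nodes)]

    def row(theta):
        fs, ksw = theta
        sys = pools.with_solute_params(fs, ksw, index=solute_index)
        try:
            return simulate_schedule(sys, schedule, ensemble).values
        except Exception as exc:  # attach node coordinates for diagnosis
            raise RuntimeError(f"simulation failed at node (fs={fs}, ksw={ksw})") from exc

    if n_jobs == 1:
        rows = [row(t) for t in thetas]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(row)(t) for t in thetas)
    signals = np.vstack(rows)
    norms = np.linalg.norm(signals, axis=1)
    return Dictionary(grid=grid, signals=signals, schedule=schedule, norms=norms)


def node_neighbors(grid: ParameterGrid, index: int) -> dict:
    """±1 neighbors of a node along each θ axis, with one-sided flags.

    Returns ``{"fs": (lo, hi, one_sided), "ksw": (lo, hi, one_sided)}``
    where ``lo``/``hi`` are node indices (None beyond the boundary).
    """
    i, j = grid.node_coords(index)
    nf, nk = grid.shape
    out = {}
    for axis, pos, size in (("fs", i, nf), ("ksw", j, nk)):
        lo = pos - 1 if pos > 0 else None
        hi = pos + 1 if pos < size - 1 else None
        if axis == "fs":
            lo_idx = grid.node_index(lo, j) if lo is not None else None
            hi_idx = grid.node_index(hi, j) if hi is not None else None
        else:
            lo_idx = grid.node_index(i, lo) if lo is not None else None
            hi_idx = grid.node_index(i, hi) if hi is not None else None
        out[axis] = (lo_idx, hi_idx, lo is None or hi is None)
    return out


def save_dictionary(dictionary: Dictionary, npz_path, fixed_params: dict | None = None) -> None:
    """Persist as NPZ plus a JSON sidecar of the fixed tissue parameters."""
    from .sequence_model import schedule_to_dict

    np.savez(
        npz_path,
        signals=dictionary.signals,
        fs_values=dictionary.grid.fs_values,
        ksw_values=dictionary.grid.ksw_values,
        norms=dictionary.norms,
    )
    sidecar = str(npz_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "schedule": schedule_to_dict(dictionary.schedule),
                "fixed_params": fixed_params or {},
            },
            fh,
            indent=2,
        )
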