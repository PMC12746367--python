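"""Cramér–Rao-bound objective over the MRF dictionary.

For a Gaussian signal model s[n; θ] + N(0, σ²) the Fisher information is

    I(θ) = (1/σ²) Σₙ (∂s[n]/∂θ)ᵀ (∂s[n]/∂θ),

with the trajectory derivative taken as a two-point finite difference on
the dictionary grid itself.  The normalized CRB divides the inverse
Fisher matrix by the parameter scale — by θᵢ² by default (dimensionless
relative variance, which makes fs ≈ 10⁻³ and ksw ≈ 10³ s⁻¹ commensurate
under equal weights), or literally by θᵢ.  The optimization loss is the
trace of the normalized CRB aggregated across the dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary_engine import Dictionary, ParameterGrid, node_neighbors

__all__ = [
    "CRBConfig",
    "CRBResult",
    "UnidentifiableNodeError",
    "finite_diff_jacobian",
    "fisher_information",
    "normalized_crb",
    "crb_loss",
]


class UnidentifiableNodeError(RuntimeError):
    """Fisher matrix singular (or numerically so) at a grid node."""

    def __init__(self, theta: tuple[float, float]):
        self.theta = theta
        super().__init__(f"unidentifiable at node (fs={theta[0]}, ksw={theta[1]})")


@dataclass(frozen=True)
class CRBConfig:
    """Noise level, parameter weighting and aggregation for the CRB loss.

    ``normalize_trajectories`` controls which signal enters the Fisher
    derivative.  The default differentiates the L2-normalized trajectory
    s/‖s‖ — the quantity the scale-invariant dot-product matcher actually
    compares — so the bound measures shape discriminability.  Setting it
    False differentiates the raw s[n] instead, which additionally counts
    amplitude information the matcher discards.
    """

    sigma: float = 1.0
    weights: tuple[float, float] = (1.0, 1.0)
    normalization: str = "theta_squared"  # or "theta"
    aggregation: str = "mean"  # or "sum", "max"
    include_boundary: bool = False
    normalize_trajectories: bool = True
    condition_cap: float = 1e12

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be > 0")
        if self.normalization not in ("theta", "theta_squared"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.aggregation not in ("mean", "sum", "max"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class CRBResult:
    """Per-node Fisher/nCRB matrices and the aggregated scalar loss."""

    fisher: np.ndarray  # (n_nodes, 2, 2); NaN rows for excluded nodes
    ncrb: np.ndarray  # (n_nodes, 2, 2)
    node_loss: np.ndarray  # (n_nodes,); NaN where excluded
    loss: float
    included: np.ndarray  # node indices entering the aggregation


def _grid_jacobian(
    signals: np.ndarray, grid: ParameterGrid, index: int
) -> tuple[np.ndarray, tuple[float, float]]:
    nbrs = node_neighbors(grid, index)
    i, j = grid.node_coords(index)
    cols = []
    steps = []
    for axis, pos, values in (("fs", i, grid.fs_values), ("ksw", j, grid.ksw_values)):
        lo, hi, _ = nbrs[axis]
        if lo is not None and hi is not None:
            step = values[pos + 1] - values[pos - 1]
            col = (signals[hi] - signals[lo]) / step
        elif hi is not None:
            step = values[pos + 1] - values[pos]
            col = (signals[hi] - signals[index]) / step
        elif lo is not None:
            step = values[pos] - values[pos - 1]
            col = (signals[index] - signals[lo]) / step
        else:
            raise ValueError(f"degenerate {axis} axis: no neighbors at node {index}")
        cols.append(col)
        steps.append(float(step))
    return np.column_stack(cols), (steps[0], steps[1])


def finite_diff_jacobian(
    dictionary: Dictionary, index: int, normalize: bool = False
) -> tuple[np.ndarray, tuple[float, float]]:
    """Two-point derivative of the trajectory on the grid at one node.

    Interior nodes use central differences over one grid spacing; boundary
    nodes fall back to one-sided two-point differences.  Returns the N×2
    Jacobian (columns ∂s/∂fs, ∂s/∂ksw) and the effective step per axis.
    With ``normalize`` the derivative is taken of s/‖s‖ instead of s.
    """
    signals = dictionary.signals
    if normalize:
        signals = signals / dictionary.norms[:, None]
    return _grid_jacobian(signals, dictionary.grid, index)


def fisher_information(jacobian: np.ndarray, sigma: float) -> np.ndarray:
    """I = Jᵀ·J / σ² — symmetric positive semidefinite by construction."""
    J = np.atleast_2d(np.asarray(jacobian, float))
    if not np.all(np.isfinite(J)):
        raise ValueError("jacobian contains non-finite entries")
    return (J.T @ J) / sigma**2


def normalized_crb(
    fisher: np.ndarray, theta: tuple[float, float], config: CRBConfig
) -> np.ndarray:
    """Invert the Fisher matrix and normalize by the parameter scale.

    ``theta_squared`` divides entry (i, j) by θᵢθⱼ (relative covariance);
    ``theta`` divides column j by θⱼ (the literal I⁻¹/θ reading).  Weights
    multiply the diagonal.
    """
    fisher = np.asarray(fisher, float)
    th = np.asarray(theta, float)
    # conditioning is assessed on the θ-scaled Fisher matrix D·I·D
    # (D = diag θ): the raw-unit matrix is ill-scaled whenever the
    # parameters differ by orders of magnitude, which says nothing about
    # identifiability
    scaled = fisher * np.outer(th, th)
    cond = np.linalg.cond(scaled)
    if not np.isfinite(cond) or cond > config.condition_cap:
        raise UnidentifiableNodeError(theta)
    scaled_inv = np.linalg.inv(scaled)
    if config.normalization == "theta_squared":
        ncrb = scaled_inv  # = D⁻¹·I⁻¹·D⁻¹, the relative covariance bound
    else:
        cov = scaled_inv * np.outer(th, th)  # = I⁻¹
        ncrb = cov / th[None, :]
    w = np.asarray(config.weights, float)
    ncrb = ncrb.copy()
    ncrb[np.diag_indices_from(ncrb)] *= w
    return ncrb


def crb_loss(dictionary: Dictionary, config: CRBConfig | None = None) -> CRBResult:
    """tr(nCRB) per node, aggregated over the dictionary (default: mean
    over interior nodes, which is invariant to grid size)."""
    if config is None:
        config = CRBConfig()
    grid = dictionary.grid
    n = grid.n_nodes
    fisher = np.full((n, 2, 2), np.nan)
    ncrb = np.full((n, 2, 2), np.nan)
    node_loss = np.full(n, np.nan)
    if config.include_boundary:
        included = np.arange(n)
    else:
        included = grid.interior_indices()
    if included.size == 0:
        raise ValueError("no grid nodes to aggregate over")
    signals = dictionary.signals
    if config.normalize_trajectories:
        signals = signals / dictionary.norms[:, None]
    for idx in included:
        J, _ = _grid_jacobian(signals, grid, int(idx))
        I = fisher_information(J, config.sigma)
        theta = grid.node_theta(int(idx))
        nc = normalized_crb(I, theta, config)
        fisher[idx] = I
        ncrb[idx] = nc
        node_loss[idx] = np.trace(nc)
    vals = node_loss[included]
    if config.aggregation == "mean":
        loss = float(np.mean(vals))
    elif config.aggregation == "sum":
        loss = float(np.sum(vals))
    else:
        loss = float(np.max(vals))
    return CRBResult(fisher=fisher, ncrb=ncrb, node_loss=node_loss, loss=loss, included=included)


def export_node_losses(result: CRBResult, grid: ParameterGrid) -> dict:
    """JSON-ready mapping of ``"fs,ksw"`` → node trace loss."""
    out = {}
    for idx in result.included:
        fs, ksw = grid.node_theta(int(idx))
        out[f"{fs:.6g},{ksw:.6g}"] = float(result.node_loss[idx])
    return out
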