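"""Per-pixel (fs, ksw) quantification by dot-product dictionary matching.

Each measured trajectory e is compared against every dictionary row d by
the normalized dot product ⟨e, d⟩ / (‖e‖·‖d‖) and assigned the grid node
of the best-matching entry.  Estimates therefore take values only from
the dictionary grid; there is no interpolation between nodes.  Ties are
broken by the lowest row-major row index; negative scores are allowed
(score ∈ [−1, 1], no absolute value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary_engine import Dictionary

__all__ = ["TrajectoryImage", "ParameterMaps", "match_pixel", "reconstruct_maps"]


@dataclass(frozen=True)
class TrajectoryImage:
    """(rows, cols, N) stack of per-pixel signal trajectories plus a mask."""

    data: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, float)
        mask = np.asarray(self.mask, bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        if data.ndim != 3:
            raise ValueError("data must have shape (rows, cols, N)")
        if mask.shape != data.shape[:2]:
            raise ValueError("mask shape must match the image plane")


@dataclass(frozen=True)
class ParameterMaps:
    """Matched (fs, ksw) per pixel with the winning cosine score.

    ``unmatched`` marks masked pixels whose trajectory had zero norm; their
    map entries are NaN.
    """

    fs_map: np.ndarray
    ksw_map: np.ndarray
    match_score: np.ndarray
    unmatched: np.ndarray
    dictionary: Dictionary


def match_pixel(e: np.ndarray, dictionary: Dictionary) -> tuple[float, float, float]:
    """Best-matching grid node for one trajectory.

    Returns (fs, ksw, score) where score is the maximal normalized dot
    product.  Raises on a zero-norm trajectory.
    """
    e = np.asarray(e, float)
    if e.size != dictionary.signals.shape[1]:
        raise ValueError("trajectory length does not match the dictionary")
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ValueError("zero-norm trajectory is unmatchable")
    scores = dictionary.signals @ e / (norm * dictionary.norms)
    idx = int(np.argmax(scores))  # first maximum = lowest row-major index
    fs, ksw = dictionary.grid.node_theta(idx)
    return fs, ksw, float(scores[idx])


def reconstruct_maps(image: TrajectoryImage, dictionary: Dictionary) -> ParameterMaps:
    """Vectorized dot-product matching over every masked pixel.

    Deterministic and order-independent; zero-norm pixels are flagged in
    ``unmatched`` and left NaN in the maps.
    """
    if not image.mask.any():
        raise ValueError("mask is empty")
    shape = image.mask.shape
    fs_map = np.full(shape, np.nan)
    ksw_map = np.full(shape, np.nan)
    score_map = np.full(shape, np.nan)
    unmatched = np.zeros(shape, bool)

    E = image.data[image.mask]  # (P, N)
    norms = np.linalg.norm(E, axis=1)
    ok = norms > 0
    D = dictionary.signals / dictionary.norms[:, None]  # (R, N)
    if ok.any():
        scores = (E[ok] / norms[ok, None]) @ D.T  # (P_ok, R)
        best = np.argmax(scores, axis=1)
        fs_axis = dictionary.grid.fs_values
        ksw_axis = dictionary.grid.ksw_values
        n_ksw = ksw_axis.size
        fs_vals = fs_axis[best // n_ksw]
        ksw_vals = ksw_axis[best % n_ksw]
        best_scores = scores[np.arange(best.size), best]
    rows, cols = np.nonzero(image.mask)
    if ok.any():
        fs_map[rows[ok], cols[ok]] = fs_vals
        ksw_map[rows[ok], cols[ok]] = ksw_vals
        score_map[rows[ok], cols[ok]] = best_scores
    unmatched[rows[~ok], cols[~ok]] = True
    return ParameterMaps(
        fs_map=fs_map,
        ksw_map=ksw_map,
        match_score=score_map,
        unmatched=unmatched,
        dictionary=dictionary,
    )
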