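"""Digital phantoms with known (fs, ksw) truth and evaluation metrics.

The vial-grid layout mimics concentration phantoms (e.g., L-arginine in
PBS at tens to hundreds of mM placed in small vials); the two-tissue
layout is a crude stand-in for white/gray matter contrast.  The solute
proton fraction is derived from the molar concentration by the
convention fs = n_protons·[c in M]/111 with n_protons = 3 for the
L-arginine guanidinium group and a 111 M water-proton pool.

Noise is additive Gaussian on the magnitude signal — the same noise model
the CRB objective assumes — so that evaluation and design share one
statistical model.  Metrics: per-ROI MAPE, range-normalized RMSE, SSIM,
Pearson r, and a two-tailed paired t-test with the usual star notation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .bm_simulator import IsochromatEnsemble, simulate_schedule
from .quantification import TrajectoryImage
from .sequence_model import AcquisitionSchedule, PoolSystem

__all__ = [
    "DigitalPhantom",
    "MetricReport",
    "concentration_to_fs",
    "make_phantom",
    "simulate_acquisition",
    "mape",
    "nrmse",
    "ssim_and_pearson",
    "paired_ttest",
]

#: Labile protons per solute molecule (guanidinium group of L-arginine).
N_PROTONS = 3
#: Water proton concentration, mol/L.
WATER_PROTON_M = 111.0


def concentration_to_fs(conc_mm: float, n_protons: int = N_PROTONS) -> float:
    """Solute proton volume fraction from millimolar concentration."""
    return n_protons * (conc_mm * 1e-3) / WATER_PROTON_M


@dataclass(frozen=True)
class DigitalPhantom:
    layout: str  # "vial_grid" or "two_tissue"
    fs_truth: np.ndarray
    ksw_truth: np.ndarray
    roi_labels: np.ndarray  # 0 = background, excluded from every metric
    pool_template: PoolSystem

    @property
    def mask(self) -> np.ndarray:
        return self.roi_labels > 0


def make_phantom(
    layout: str,
    concentrations: list[float],
    ksw_values: list[float],
    size: int,
    pool_template: PoolSystem,
    fs_values: list[float] | None = None,
) -> DigitalPhantom:
    """Build a digital phantom with piecewise-constant truth maps.

    ``vial_grid``: circular vials on a square grid, one (fs, ksw) pair per
    vial.  ``two_tissue``: two interleaved block regions using the first
    two (fs, ksw) pairs.  ``fs_values`` overrides the concentration-derived
    fractions when given (e.g., semisolid MT fractions).
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if fs_values is None:
        fs_values = [concentration_to_fs(c) for c in concentrations]
    if len(fs_values) != len(ksw_values):
        raise ValueError("fs/concentration and ksw lists must have equal length")
    if any(f <= 0 for f in fs_values):
        raise ValueError("every vial must have fs > 0 (zero-concentration vials rejected)")

    fs_truth = np.zeros((size, size))
    ksw_truth = np.zeros((size, size))
    labels = np.zeros((size, size), int)
    yy, xx = np.mgrid[0:size, 0:size]

    if layout == "vial_grid":
        n = len(fs_values)
        ncols = int(np.ceil(np.sqrt(n)))
        nrows = int(np.ceil(n / ncols))
        cell = size / max(ncols, nrows)
        radius = 0.35 * cell
        if radius < 2:
            raise ValueError(f"vials do not fit: {n} vials at size {size}")
        for v in range(n):
            r, c = divmod(v, ncols)
            cy = (r + 0.5) * size / nrows
            cx = (c + 0.5) * size / ncols
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            labels[disk] = v + 1
            fs_truth[disk] = fs_values[v]
            ksw_truth[disk] = ksw_values[v]
    elif layout == "two_tissue":
        if len(fs_values) < 2:
            raise ValueError("two_tissue layout needs two (fs, ksw) pairs")
        cy = cx = (size - 1) / 2
        brain = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.45 * size) ** 2
        block = max(4, size // 8)
        check = ((yy // block + xx // block) % 2).astype(int)
        labels[brain] = 1 + check[brain]
        for lab in (1, 2):
            fs_truth[labels == lab] = fs_values[lab - 1]
            ksw_truth[labels == lab] = ksw_values[lab - 1]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return DigitalPhantom(
        layout=layout,
        fs_truth=fs_truth,
        ksw_truth=ksw_truth,
        roi_labels=labels,
        pool_template=pool_template,
    )


def simulate_acquisition(
    phantom: DigitalPhantom,
    schedule: AcquisitionSchedule,
    sigma: float,
    seed: int | np.random.Generator,
    ensemble: IsochromatEnsemble | None = None,
) -> TrajectoryImage:
    """Noisy synthetic acquisition of the phantom under a schedule.

    Each distinct (fs, ksw) truth pair is simulated once and broadcast to
    its pixels, then i.i.d. N(0, σ) noise is added per pixel and sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = phantom.mask
    n = len(schedule)
    data = np.zeros(mask.shape + (n,))
    pairs = {}
    for fs, ksw in zip(phantom.fs_truth[mask], phantom.ksw_truth[mask]):
        pairs[(float(fs), float(ksw))] = None
    for fs, ksw in pairs:
        sys = phantom.pool_template.with_solute_params(fs, ksw)
        pairs[(fs, ksw)] = simulate_schedule(sys, schedule, ensemble).values
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        data[r, c] = pairs[(float(phantom.fs_truth[r, c]), float(phantom.ksw_truth[r, c]))]
    if sigma > 0:
        data[mask] += rng.normal(0.0, sigma, size=(mask.sum(), n))
    return TrajectoryImage(data=data, mask=mask)


def mape(true_map: np.ndarray, est_map: np.ndarray, roi_labels: np.ndarray) -> dict[int, float]:
    """Mean absolute percentage error, 100·mean(|est−true|/true), per ROI."""
    out = {}
    for lab in np.unique(roi_labels):
        if lab == 0:
            continue
        sel = roi_labels == lab
        t = true_map[sel]
        e = est_map[sel]
        if np.any(t == 0):
            raise ValueError(f"ROI {lab}: truth contains zeros, MAPE undefined")
        out[int(lab)] = float(100.0 * np.mean(np.abs(e - t) / np.abs(t)))
    if not out:
        raise ValueError("no nonzero ROI labels")
    return out


def mape_mean(true_map: np.ndarray, est_map: np.ndarray, roi_labels: np.ndarray) -> float:
    """Mean of per-ROI MAPE values (each vial weighted equally)."""
    return float(np.mean(list(mape(true_map, est_map, roi_labels).values())))


def nrmse(reference_map: np.ndarray, est_map: np.ndarray, mask: np.ndarray) -> float:
    """RMSE over masked pixels divided by the reference range (max − min)."""
    ref = reference_map[mask]
    est = est_map[mask]
    rng = ref.max() - ref.min()
    if rng == 0:
        raise ValueError("reference map is constant within the mask")
    return float(np.sqrt(np.mean((ref - est) ** 2)) / rng)


def ssim_and_pearson(
    reference_map: np.ndarray, est_map: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """SSIM (K1=0.01, K2=0.03, 7-pixel window, data range = reference range
    in the mask) over the full maps with background zeroed, and Pearson r
    over the masked pixels."""
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    ref = reference_map[mask]
    if np.std(ref) == 0 or np.std(est_map[mask]) == 0:
        raise ValueError("zero variance within the mask; correlation undefined")
    data_range = float(ref.max() - ref.min())
    ref_img = np.where(mask, reference_map, 0.0)
    est_img = np.where(mask, est_map, 0.0)
    ssim = float(
        structural_similarity(ref_img, est_img, win_size=7, data_range=data_range)
    )
    r = float(stats.pearsonr(reference_map[mask], est_map[mask]).statistic)
    return ssim, r


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def paired_ttest(
    metric_before: list[float], metric_after: list[float]
) -> tuple[float, float, str]:
    """Two-tailed paired t-test with significance stars.

    Identical lists return (0, 1, "ns") by convention; constant nonzero
    differences have no variance and raise.
    """
    a = np.asarray(metric_before, float)
    b = np.asarray(metric_after, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    diffs = a - b
    if np.std(diffs) == 0:
        if np.all(diffs == 0):
            return 0.0, 1.0, "ns"
        raise ValueError("differences are constant and nonzero; t undefined")
    res = stats.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    stars = "ns"
    for level, s in _STAR_LEVELS:
        if p < level:
            stars = s
            break
    return t, p, stars


@dataclass
class MetricReport:
    """Bundle of all evaluation metrics for one reconstructed map pair."""

    mape_fs: dict[int, float]
    mape_ksw: dict[int, float]
    mape_fs_mean: float
    mape_ksw_mean: float
    nrmse_fs: float
    nrmse_ksw: float
    ssim_fs: float
    ssim_ksw: float
    pearson_fs: float
    pearson_ksw: float

    def to_dict(self) -> dict:
        return {
            "mape_fs_per_roi": {str(k): v for k, v in self.mape_fs.items()},
            "mape_ksw_per_roi": {str(k): v for k, v in self.mape_ksw.items()},
            "mape_fs_mean": self.mape_fs_mean,
            "mape_ksw_mean": self.mape_ksw_mean,
            "nrmse_fs": self.nrmse_fs,
            "nrmse_ksw": self.nrmse_ksw,
            "ssim_fs": self.ssim_fs,
            "ssim_ksw": self.ssim_ksw,
            "pearson_fs": self.pearson_fs,
            "pearson_ksw": self.pearson_ksw,
        }


def evaluate_maps(phantom: DigitalPhantom, maps) -> MetricReport:
    """All metrics of estimated maps against the phantom truth."""
    mask = phantom.mask & ~maps.unmatched
    labels = np.where(mask, phantom.roi_labels, 0)
    ssim_fs, r_fs = ssim_and_pearson(phantom.fs_truth, np.nan_to_num(maps.fs_map), mask)
    ssim_ksw, r_ksw = ssim_and_pearson(phantom.ksw_truth, np.nan_to_num(maps.ksw_map), mask)
    return MetricReport(
        mape_fs=mape(phantom.fs_truth, maps.fs_map, labels),
        mape_ksw=mape(phantom.ksw_truth, maps.ksw_map, labels),
        mape_fs_mean=mape_mean(phantom.fs_truth, maps.fs_map, labels),
        mape_ksw_mean=mape_mean(phantom.ksw_truth, maps.ksw_map, labels),
        nrmse_fs=nrmse(phantom.fs_truth, np.nan_to_num(maps.fs_map), mask),
        nrmse_ksw=nrmse(phantom.ksw_truth, np.nan_to_num(maps.ksw_map), mask),
        ssim_fs=ssim_fs,
        ssim_ksw=ssim_ksw,
        pearson_fs=r_fs,
        pearson_ksw=r_ksw,
    )
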