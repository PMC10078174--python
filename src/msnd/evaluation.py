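"""Quantitative evaluation: CoV, ADC fitting, recovery metrics, comparators."""
from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .core import smooth_phase
from .encoding import ShotPhaseMaps, WaterFatImage
from .simulator import PhantomGroundTruth, attenuated_truth


def coefficient_of_variation(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """SD/mean of the signal magnitude within a region of interest.

    Uses the sample standard deviation (divisor n-1). Raises on an empty ROI
    or a zero mean.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    vals = np.abs(np.asarray(image))[roi_mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero-mean ROI")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(sd / mean)


def fit_adc(images: Sequence[np.ndarray], bvalues: Sequence[float]) -> np.ndarray:
    """Voxelwise mono-exponential ADC map from per-b magnitude images.

    Least-squares line fit of ``ln S`` against ``b`` using all b-values
    jointly; ADC (in the units implied by 1/b) is minus the slope. Voxels
    with any nonpositive signal are invalid (NaN) rather than clipped.
    """
    b = np.asarray(bvalues, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two b-values")
    stack = np.stack([np.abs(np.asarray(im), dtype=float) for im in images])
    if stack.shape[0] != b.size:
        raise ValueError("number of images and b-values disagree")
    valid = np.all(stack > 0, axis=0)
    logs = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    design = np.stack([np.ones_like(b), -b], axis=1)
    coef = np.linalg.pinv(design) @ logs.reshape(b.size, -1)
    adc = coef[1].reshape(stack.shape[1:])
    adc = np.where(valid, adc, np.nan)
    return adc


def fit_adc_two_point(images: Sequence[np.ndarray], bvalues: Sequence[float]) -> np.ndarray:
    """Two-point ADC from the first and last b-values (parity-check mode)."""
    b = np.asarray(bvalues, dtype=float)
    s0, s1 = np.abs(images[0]), np.abs(images[-1])
    valid = (s0 > 0) & (s1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s0 / s1) / (b[-1] - b[0])
    return np.where(valid, adc, np.nan)


def nrmse(estimate: np.ndarray, reference: np.ndarray) -> float:
    """||estimate - reference|| / ||reference||."""
    return float(
        np.linalg.norm(estimate - reference) / np.linalg.norm(reference)
    )


def align_global_scale(recon: WaterFatImage, truth: WaterFatImage) -> WaterFatImage:
    """Remove the global complex scale (gauge) between a recovery and truth.

    The joint least-squares scale over both species is applied; a shared
    constant phase between images and shot phase maps leaves the data
    invariant, so comparisons are only meaningful after this alignment.
    """
    num = np.vdot(recon.water, truth.water) + np.vdot(recon.fat, truth.fat)
    den = np.vdot(recon.water, recon.water) + np.vdot(recon.fat, recon.fat)
    alpha = num / den if abs(den) > 0 else 1.0
    return WaterFatImage(alpha * recon.water, alpha * recon.fat)


def masked_phase_rmse(
    recon: ShotPhaseMaps, truth: ShotPhaseMaps, support: np.ndarray
) -> float:
    """RMS wrapped phase error (rad) on support, per-map constant removed."""
    support = np.asarray(support, dtype=bool)
    errs = []
    for n in range(truth.shape[0]):
        for l in range(truth.shape[1]):
            d = np.angle(np.exp(1j * (recon.phases[n, l] - truth.phases[n, l])))
            c = np.angle(np.mean(np.exp(1j * d[support])))
            errs.append(np.angle(np.exp(1j * (d[support] - c))))
    return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))


def fat_leakage_ratio(
    recon_water: np.ndarray,
    truth: PhantomGroundTruth,
    bvalue: float = 0.0,
    statistic: str = "mean",
) -> float:
    """Spurious water signal in fat-only regions, relative to water max.

    Fat-only voxels are those with fat signal but (numerically) no water in
    the ground truth; residual water signal there is fat that leaked through
    the separation. ``statistic`` is ``"mean"`` (mean spurious magnitude over
    the region, robust to single noise voxels) or ``"max"`` (worst voxel);
    both are normalized by the peak true water magnitude at this b-value.
    """
    x = attenuated_truth(truth, bvalue)
    fat_only = (np.abs(truth.fat) > 0.1 * np.abs(truth.fat).max()) & (
        np.abs(truth.water) < 1e-9
    )
    if not fat_only.any():
        raise ValueError("phantom has no fat-only region")
    vals = np.abs(recon_water)[fat_only]
    stat = vals.mean() if statistic == "mean" else vals.max()
    return float(stat / np.abs(x.water).max())


def recovery_report(
    truth: PhantomGroundTruth,
    recon: WaterFatImage,
    bvalue: float = 0.0,
    recon_phases: Optional[ShotPhaseMaps] = None,
    residuals: Optional[Sequence[float]] = None,
) -> Dict:
    """Machine-readable recovery metrics against the simulated ground truth.

    Reports water/fat NRMSE after global complex-scale (gauge) alignment, the
    fat-into-water leakage ratio, and — when phase maps are supplied — the
    masked phase RMSE with the per-map constant removed.
    """
    x = attenuated_truth(truth, bvalue)
    if recon.grid != x.grid:
        raise ValueError("reconstruction and truth grids disagree")
    aligned = align_global_scale(recon, x)
    report = {
        "bvalue": float(bvalue),
        "nrmse_water": nrmse(aligned.water, x.water),
        "nrmse_fat": nrmse(aligned.fat, x.fat),
        "nrmse_water_magnitude": nrmse(np.abs(recon.water), np.abs(x.water)),
        "fat_leakage_ratio": fat_leakage_ratio(recon.water, truth, bvalue),
    }
    if recon_phases is not None:
        report["phase_rmse_rad"] = masked_phase_rmse(
            recon_phases, truth.true_phases[bvalue], truth.support()
        )
    if residuals is not None:
        report["residuals"] = [float(r) for r in residuals]
    return report


def emulated_navigator_phases(
    truth: PhantomGroundTruth, bvalue: float, window_fraction: float = 0.25
) -> ShotPhaseMaps:
    """Extra-navigator-style phase maps: low-resolution view of the truth.

    Emulates a measured 2D navigator by low-pass filtering the true shot
    phase maps (a navigator is a separately acquired low-resolution image, so
    it sees only a smoothed version of the phase); used as the fixed-phase
    comparator in reconstruction comparisons.
    """
    return smooth_phase(truth.true_phases[bvalue], window_fraction)
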