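"""Region handling shared by the manual-ROI and segmentation analysis paths:
probability-mask thresholding, normal-appearing-white-matter mask algebra,
region-mean curve extraction, and scanner signal-drift estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .relaxometry import ConcentrationSeries, DynamicSeries

__all__ = [
    "RegionSpec",
    "threshold_probability_mask",
    "nawm_mask",
    "mean_curve",
    "estimate_drift",
]

logger = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    """A named voxel region with its provenance (manual ROI or segmentation)."""

    name: str
    mask: np.ndarray
    source: Literal["manual_roi", "segmentation"] = "segmentation"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_voxels == 0:
            raise ValueError(f"region {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def threshold_probability_mask(prob_map: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Binarize a tissue probability map: voxel included iff p >= threshold.

    The default threshold of 1.0 (100% probability) gives zero tolerance for
    partial-volume voxels.  An empty result is allowed but logged.
    """
    p = np.asarray(prob_map, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    mask = p >= threshold
    if not mask.any():
        logger.warning("probability threshold %.3g produced an empty mask", threshold)
    return mask


def nawm_mask(wm_mask: np.ndarray, lesion_prob: np.ndarray) -> np.ndarray:
    """Normal-appearing white matter: WM voxels with exactly zero lesion probability.

    The lesion exclusion is strict equality with zero — any non-zero lesion
    probability removes the voxel.
    """
    wm = np.asarray(wm_mask, dtype=bool)
    lp = np.asarray(lesion_prob, dtype=float)
    if wm.shape != lp.shape:
        raise ValueError("WM mask and lesion probability map shapes differ")
    return wm & (lp == 0)


def mean_curve(
    series: DynamicSeries | ConcentrationSeries,
    region: RegionSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted region-mean curve, one value per frame.

    Invalid (NaN) voxels are excluded per frame; the second return value is
    the per-frame count of voxels that contributed.

    Raises
    ------
    ValueError
        If the region is empty, or empty at some frame after validity
        filtering.
    """
    data = series.signal if isinstance(series, DynamicSeries) else series.conc_mM
    mask = region.mask
    if mask.shape != data.shape[:-1]:
        raise ValueError("region mask shape must match the image grid")
    vox = data.reshape(-1, data.shape[-1])[mask.reshape(-1)]
    finite = np.isfinite(vox)
    n_used = finite.sum(axis=0)
    if np.any(n_used == 0):
        raise ValueError(f"region {region.name!r} has no valid voxels at some frame")
    mean = np.where(finite, vox, 0.0).sum(axis=0) / n_used
    return mean, n_used


def estimate_drift(series: DynamicSeries, region: RegionSpec) -> float:
    """Scanner signal drift of a contrast-free series, in percent per minute.

    An OLS line is fitted to the region-mean signal against time; the slope
    is normalized to the fitted intercept (signal at t = 0) and expressed in
    % min^-1.  Drift is reported, not corrected, by the main pipeline.
    """
    s, _ = mean_curve(series, region)
    if s.size < 2:
        raise ValueError("need at least 2 frames to estimate drift")
    t = series.time_s / 60.0
    slope, intercept = np.polyfit(t, s, 1)
    if intercept <= 0:
        raise ValueError("zero or negative baseline signal; drift undefined")
    return 100.0 * slope / intercept


def apply_drift_correction(series: DynamicSeries, drift_pct_per_min: float) -> DynamicSeries:
    """Divide out a multiplicative linear drift (off by default in the pipeline)."""
    t = series.time_s / 60.0
    factor = 1.0 + drift_pct_per_min / 100.0 * t
    return DynamicSeries(signal=series.signal / factor, params=series.params, time_s=series.time_s)
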