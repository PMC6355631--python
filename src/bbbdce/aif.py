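"""Arterial input function extraction.

The AIF is measured per subject from an arterial region of interest
(typically the supraclinoid internal carotid) by selecting the voxel with
the maximal positive signal excursion from its pre-injection baseline during
bolus passage, then converting that voxel's signal-time course to
whole-blood gadolinium concentration through the relaxometry layer.

No hematocrit scaling is applied: the influx constant downstream is defined
relative to the whole-blood tracer concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxometry import (
    AcquisitionParams,
    ConcentrationSeries,
    DynamicSeries,
    T1M0Map,
    signal_to_concentration,
)

__all__ = ["Aif", "NoBolusError", "extract_aif"]


class NoBolusError(RuntimeError):
    """Raised when no masked voxel shows a positive bolus excursion."""


@dataclass
class Aif:
    """Arterial whole-blood concentration-time curve.

    Attributes
    ----------
    conc_mM : (n_frames,) array, whole-blood gadolinium concentration.
    time_min : (n_frames,) array, frame mid-times in minutes.
    source_voxel : flat index (into the masked image grid) of the selected voxel,
        or -1 for synthetic / externally supplied curves.
    peak_frame : 0-based index of the concentration maximum.
    """

    conc_mM: np.ndarray
    time_min: np.ndarray
    source_voxel: int = -1
    peak_frame: int = 0

    def __post_init__(self) -> None:
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.conc_mM.shape != self.time_min.shape:
            raise ValueError("conc and time must share a shape")


def extract_aif(
    series: DynamicSeries,
    artery_mask: np.ndarray,
    t1m0: T1M0Map,
    params: AcquisitionParams | None = None,
) -> Aif:
    """Select the arterial voxel with maximal signal change and return its AIF.

    For every masked voxel the signal change is the maximum over frames of
    ``S(t) - baseline``, with the baseline the mean over the pre-injection
    frames.  The selection is therefore invariant to constant offsets.  Ties
    break to the lowest flat voxel index.

    Raises
    ------
    ValueError
        Empty mask, or mask shape not matching the image grid.
    NoBolusError
        No masked voxel enhances above its baseline.
    RuntimeError
        The selected voxel's conversion is invalid at the bolus peak.
    """
    p = params or series.params
    mask = np.asarray(artery_mask, dtype=bool)
    if mask.shape != series.signal.shape[:-1]:
        raise ValueError("artery mask shape must match the image grid")
    idx = np.flatnonzero(mask.reshape(-1))
    if idx.size == 0:
        raise ValueError("artery mask is empty")

    sig = series.signal.reshape(-1, series.n_frames)[idx]
    baseline = sig[:, series.baseline_frames].mean(axis=1, keepdims=True)
    change = (sig - baseline).max(axis=1)
    if np.all(change <= 0):
        raise NoBolusError("no bolus detected: no masked voxel enhances above baseline")
    best = int(idx[int(np.argmax(change))])

    one = DynamicSeries(
        signal=series.signal.reshape(-1, series.n_frames)[best][None, :],
        params=p,
        time_s=series.time_s,
    )
    flat_t1m0 = T1M0Map(
        t1_ms=np.asarray(t1m0.t1_ms).reshape(-1)[best][None],
        m0=np.asarray(t1m0.m0).reshape(-1)[best][None],
        fit_ok=np.asarray(t1m0.fit_ok).reshape(-1)[best][None],
    )
    conc = signal_to_concentration(one, flat_t1m0, p)
    curve = conc.conc_mM[0]
    valid = conc.valid[0]
    peak = int(np.nanargmax(np.where(valid, curve, -np.inf)))
    if not valid[peak]:
        raise RuntimeError(f"AIF conversion invalid at peak for voxel {best}")
    # Pre-injection frames of a valid AIF are ~0; NaNs elsewhere are kept.
    return Aif(conc_mM=curve, time_min=conc.time_min, source_voxel=best, peak_frame=peak)
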