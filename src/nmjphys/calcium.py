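"""Single-AP calcium transient analysis for line-scan imaging.

Fluorescence changes are quantified as

    dFF(t) = (F(t) - F_baseline) / (F_baseline - F_background)

where F_baseline is the mean ROI fluorescence over the 300 ms preceding the
stimulus and F_background the mean of an indicator-free background ROI over
the same window.  Recordings are excluded when the resting fluorescence
decreases by more than 15% across the record or when F_baseline exceeds
650 a.u. (both thresholds strict: a value exactly at the limit is kept; the
650 a.u. cutoff is hardware-specific and configurable).  A bouton's transient
is the pointwise mean of 8-12 accepted line scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .trace import Trace

__all__ = [
    "CalciumTransient",
    "ImagingQC",
    "BASELINE_WINDOW_S",
    "dff",
    "imaging_qc",
    "average_transients",
    "normalize_shape",
]

BASELINE_WINDOW_S = 0.300      # pre-stimulus baseline averaging window
DRIFT_LIMIT = 0.15             # exclude if resting fluorescence drops by more
F_BASELINE_LIMIT = 650.0       # a.u.; exclude above this resting fluorescence


@dataclass
class ImagingQC:
    """Exclusion decision for one line-scan recording."""

    excluded: bool
    reason: str                 # "drift_gt_15pct" | "baseline_gt_650" | "none"
    drift: float                # fractional decrease of resting fluorescence
    f_baseline: float


@dataclass
class CalciumTransient:
    """Averaged single-bouton calcium transient."""

    dff_trace: Trace
    f_baseline: float
    f_background: float
    peak_dff: float
    n_scans_averaged: int
    excluded: bool = False
    exclusion_reason: str = "none"
    flags: list[str] = field(default_factory=list)


def _baseline_window(stim_time_s: float) -> tuple[float, float]:
    return (stim_time_s - BASELINE_WINDOW_S, stim_time_s)


def _require_same_grid(a: Trace, b: Trace) -> None:
    if abs(a.dt - b.dt) > 1e-12 or a.samples.size != b.samples.size or abs(a.t0 - b.t0) > 1e-12:
        raise ParameterError("traces must share the same time grid")


def dff(roi: Trace, background: Trace, stim_time_s: float) -> Trace:
    """Compute the dFF trace of one line scan.

    The ratio form makes the result invariant to a common gain on both ROI
    and background.  Raises when F_baseline <= F_background (degenerate
    denominator) or when the 300-ms baseline window does not exist.
    """
    _require_same_grid(roi, background)
    if stim_time_s - roi.t0 < BASELINE_WINDOW_S:
        raise ParameterError("stimulus must be >= 300 ms into the record")
    w = _baseline_window(stim_time_s)
    f_base = float(np.mean(roi.slice(*w)))
    f_bg = float(np.mean(background.slice(*w)))
    if f_base <= f_bg:
        raise ParameterError(
            f"degenerate denominator: F_baseline={f_base:.3g} <= F_background={f_bg:.3g}")
    out = (roi.samples - f_base) / (f_base - f_bg)
    return Trace(out, dt=roi.dt, t0=roi.t0, channel="fluorescence_au", label="dff")


def imaging_qc(roi: Trace, stim_time_s: float,
               *,
               drift_limit: float = DRIFT_LIMIT,
               f_baseline_limit: float = F_BASELINE_LIMIT,
               transient_mask_s: float = 0.75) -> ImagingQC:
    """Exclusion rule for one recording, a pure function of the trace.

    Drift is the fractional decrease of the resting fluorescence across the
    whole record: a straight line is fit to the ROI samples with the
    transient window [stim, stim + ``transient_mask_s``) masked out, and
    drift = (line(start) - line(end)) / line(start).  Excluded when
    drift > ``drift_limit`` (strictly) or when the 300-ms pre-stimulus
    F_baseline > ``f_baseline_limit`` (strictly).
    """
    t = roi.times
    resting = ~((t >= stim_time_s) & (t < stim_time_s + transient_mask_s))
    if np.count_nonzero(resting) < 4:
        raise ParameterError("record too short to estimate resting-fluorescence drift")
    slope, intercept = np.polyfit(t[resting], roi.samples[resting], 1)
    f_start = float(slope * t[0] + intercept)
    f_end = float(slope * t[-1] + intercept)
    drift = (f_start - f_end) / f_start if f_start != 0 else 0.0
    f_base = float(np.mean(roi.slice(*_baseline_window(stim_time_s))))
    if drift > drift_limit:
        return ImagingQC(True, "drift_gt_15pct", drift, f_base)
    if f_base > f_baseline_limit:
        return ImagingQC(True, "baseline_gt_650", drift, f_base)
    return ImagingQC(False, "none", drift, f_base)


def average_transients(transients: Sequence[Trace], stim_time_s: float,
                       *,
                       f_baseline: float = float("nan"),
                       f_background: float = float("nan")) -> CalciumTransient:
    """Pointwise mean of per-scan dFF traces; peak is the post-stimulus max.

    The standard protocol averages 8-12 line scans; fewer than 8 yields a
    warning flag but the average is still computed.
    """
    transients = list(transients)
    if not transients:
        raise ParameterError("need at least one transient")
    ref = transients[0]
    for tr in transients[1:]:
        _require_same_grid(ref, tr)
    mean = np.mean([tr.samples for tr in transients], axis=0)
    avg = Trace(mean, dt=ref.dt, t0=ref.t0, channel="fluorescence_au", label="dff_avg")
    post = avg.samples[avg.times >= stim_time_s]
    if post.size == 0:
        raise ParameterError("no samples after the stimulus")
    flags = []
    if len(transients) < 8:
        flags.append("fewer_than_8_scans")
    elif len(transients) > 12:
        flags.append("more_than_12_scans")
    return CalciumTransient(avg, f_baseline, f_background, float(np.max(post)),
                            len(transients), flags=flags)


def normalize_shape(transient: CalciumTransient) -> Trace:
    """dFF trace divided by its peak, for amplitude-independent shape
    comparison across genotypes; the output peak is exactly 1.0."""
    if not (transient.peak_dff > 0):
        raise ParameterError("cannot normalize a transient with non-positive peak")
    return transient.dff_trace.with_samples(
        transient.dff_trace.samples / transient.peak_dff, label="dff_norm")
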