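"""Miniature-event detection and statistics, quantal content, and recording
acceptance rules.

Quantal content of a recording is the ratio of its mean evoked EPSP to its
mean mEPSP amplitude; the genotype-level value is the mean of per-recording
quantal contents, never the ratio of genotype means.  No nonlinear-summation
correction is applied to EPSP amplitudes: quantal content is the raw ratio.

Mini detection is a threshold-on-smoothed-derivative algorithm followed by
peak-minus-local-baseline amplitude measurement.  Default parameters:
amplitude threshold 4x the robust noise SD, minimum inter-event interval
10 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .trace import Trace, lowpass

__all__ = [
    "MiniEvent",
    "MiniStats",
    "RecordingSummary",
    "VmDecision",
    "detect_minis",
    "mini_stats",
    "quantal_content",
    "genotype_quantal_content",
    "recording_qc",
    "robust_noise_sd",
]


@dataclass
class MiniEvent:
    """A detected spontaneous miniature event."""

    t_peak: float          # s
    amplitude: float       # mV or nA, magnitude
    rise_ms: float         # 20-80% rise time
    decay_ms: float        # peak -> 1/e decay time

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ParameterError("MiniEvent amplitude must be > 0")


@dataclass
class MiniStats:
    """Summary statistics of a miniature-event population."""

    amp_mean: float
    amp_sem: float
    n_events: int
    frequency_hz: float
    cumulative: pd.DataFrame    # columns amplitude, cum_fraction (right-continuous ECDF)
    flags: list[str] = field(default_factory=list)


@dataclass
class RecordingSummary:
    """Per-NMJ summary: quantal size, evoked amplitude, quantal content."""

    mepsp_mean: float
    mepsp_n: int
    epsp_mean: float
    epsp_n: int
    quantal_content: float
    vm_rest_mV: float
    accepted: bool = True
    clamp_target_mV: float | None = None


class VmDecision(Enum):
    """Acceptance decision for a muscle recording given its resting Vm."""

    RECORD_AT_VM = "record_at_vm"
    CLAMP_TO_MINUS_65 = "clamp_to_minus_65"
    DISCARD = "discard"


def robust_noise_sd(samples: np.ndarray) -> float:
    """Noise SD estimated from the median absolute first difference.

    Insensitive to sparse large events; for white Gaussian noise the median
    |diff| equals sqrt(2) * sd * 0.6745.
    """
    d = np.abs(np.diff(np.asarray(samples, dtype=float)))
    return float(np.median(d) / (0.6744897501960817 * math.sqrt(2.0)))


def detect_minis(trace: Trace,
                 threshold: float | None = None,
                 min_interval_ms: float = 10.0,
                 *,
                 smooth_hz: float = 1000.0,
                 deriv_mult: float = 3.0,
                 peak_window_ms: float = 15.0) -> list[MiniEvent]:
    """Detect spontaneous miniature events on a stimulus-free record.

    Candidates are rising-slope excursions of the low-pass-filtered trace
    exceeding ``deriv_mult`` x the robust SD of the derivative; each
    candidate's amplitude is its local peak minus the mean of a 2.5-ms
    pre-onset baseline, and candidates below ``threshold`` (default 4x the
    robust noise SD of the trace) are dropped.  Events closer than
    ``min_interval_ms`` are merged keeping the larger.  An empty result is a
    valid outcome.
    """
    dt = trace.dt
    nyq = 0.5 / dt
    sm = lowpass(trace, smooth_hz).samples if smooth_hz < 0.95 * nyq else trace.samples.copy()
    noise_sd = robust_noise_sd(trace.samples)
    if threshold is None:
        threshold = 4.0 * noise_sd
    if threshold <= 0:
        # noise-free record: fall back to a fraction of the dynamic range
        span = float(np.ptp(sm))
        if span == 0:
            return []
        threshold = 0.05 * span
    dv = np.gradient(sm, dt)
    dv_sd = float(np.median(np.abs(dv - np.median(dv)))) * 1.4826
    dv_thr = deriv_mult * dv_sd
    above = dv > dv_thr if dv_thr > 0 else dv > 0

    # contiguous runs of suprathreshold rising slope -> candidate onsets
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above.size and above[0]:
        edges = np.concatenate([[0], edges])

    w_peak = max(1, int(round(peak_window_ms / 1000.0 / dt)))
    w_base = max(1, int(round(0.0025 / dt)))
    n = sm.size
    events: list[MiniEvent] = []
    for j0 in edges:
        j1 = min(n, j0 + w_peak)
        jp = j0 + int(np.argmax(sm[j0:j1]))
        b0 = max(0, j0 - w_base)
        base = float(np.mean(sm[b0:j0])) if j0 > b0 else float(sm[j0])
        amp = float(sm[jp]) - base
        if amp < threshold or amp <= 0:
            continue
        # 20-80% rise time on the leading flank
        seg = sm[b0:jp + 1] - base
        i20 = np.argmax(seg >= 0.2 * amp)
        i80 = np.argmax(seg >= 0.8 * amp)
        rise_ms = max(0.0, (i80 - i20) * dt * 1000.0)
        # peak -> 1/e decay
        tail = sm[jp:min(n, jp + 4 * w_peak)] - base
        below = np.flatnonzero(tail <= amp / math.e)
        decay_ms = (below[0] * dt * 1000.0) if below.size else float(4 * w_peak * dt * 1000.0)
        events.append(MiniEvent(t_peak=trace.t0 + jp * dt, amplitude=amp,
                                rise_ms=rise_ms, decay_ms=decay_ms))

    # merge events closer than the refractory interval, keeping the larger
    min_gap = min_interval_ms / 1000.0
    merged: list[MiniEvent] = []
    for ev in sorted(events, key=lambda e: e.t_peak):
        if merged and ev.t_peak - merged[-1].t_peak < min_gap:
            if ev.amplitude > merged[-1].amplitude:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def mini_stats(events: Sequence[MiniEvent], duration_s: float) -> MiniStats:
    """Mean amplitude, SEM, event frequency and cumulative amplitude table."""
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    n = len(events)
    flags: list[str] = []
    if n == 0:
        flags.append("no_events")
        cum = pd.DataFrame({"amplitude": [], "cum_fraction": []})
        return MiniStats(float("nan"), float("nan"), 0, 0.0, cum, flags)
    amps = np.sort([e.amplitude for e in events])
    if n >= 2:
        sem = float(np.std(amps, ddof=1) / math.sqrt(n))
    else:
        sem = float("nan")
        flags.append("sem_undefined")
    cum = pd.DataFrame({"amplitude": amps, "cum_fraction": np.arange(1, n + 1) / n})
    return MiniStats(float(np.mean(amps)), sem, n, n / duration_s, cum, flags)


def quantal_content(epsp_mean: float, mepsp_mean: float) -> float:
    """Quantal content of one recording: mean EPSP / mean mEPSP.

    Scale-invariant: quantal_content(c*e, c*m) == quantal_content(e, m).
    """
    if epsp_mean <= 0 or mepsp_mean <= 0:
        raise ParameterError("epsp_mean and mepsp_mean must both be > 0")
    return epsp_mean / mepsp_mean


def genotype_quantal_content(recordings: Sequence[RecordingSummary]) -> float:
    """Genotype-level quantal content: mean of per-recording ratios.

    Deliberately the mean of ratios — on heterogeneous populations this
    differs from the ratio of genotype means, and the per-recording ratio is
    the defined quantity.
    """
    if not recordings:
        raise ParameterError("need at least one recording")
    return float(np.mean([r.quantal_content for r in recordings]))


def recording_qc(vm_rest_mV: float) -> tuple[VmDecision, float | None]:
    """Acceptance rule for a muscle recording from its resting potential.

    Vm <= -60 mV: record at the cell's own Vm.  -60 < Vm <= -55 mV: clamp to
    -65 mV (the Vm is more positive than -60).  Vm > -55 mV: discard.
    Boundary values sit with the more permissive outcome ("more positive /
    more depolarized than" read strictly).  Returns (decision, clamp target).
    """
    if vm_rest_mV <= -60.0:
        return VmDecision.RECORD_AT_VM, None
    if vm_rest_mV <= -55.0:
        return VmDecision.CLAMP_TO_MINUS_65, -65.0
    return VmDecision.DISCARD, None
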