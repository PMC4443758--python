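"""High-frequency train analysis: per-stimulus EPSC amplitudes,
cumulative-EPSC back-extrapolation of the readily-releasable pool (RRP),
P_train, depression decay kinetics, and the paired-pulse ratio.

The RRP estimate follows the cumulative-EPSC train method: amplitudes of a
60-Hz, 30-stimulus train are accumulated, an ordinary-least-squares line is
fit to the last 10 cumulative points (1-based points 21-30), and the line is
back-extrapolated to stimulus index 0.  The intercept is the cumulative EPSC
attributable to the initially available pool; dividing by the same-cell mean
quantal (mEPSC) amplitude converts it to vesicles.  "Time 0" lives on the
stimulus-index axis — with the uniform 16.67-ms spacing of a 60-Hz train the
time axis gives the identical intercept.

P_train, a release-probability proxy, is the first-stimulus amplitude
divided by the back-extrapolated intercept: the fraction of the total RRP
released by one action potential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import ParameterError
from .trace import Trace, SweepSet, baseline_mean

__all__ = [
    "TrainResult",
    "RRPEstimate",
    "DecayFit",
    "PTrainResult",
    "train_amplitudes",
    "estimate_rrp",
    "p_train",
    "depression_decay_fit",
    "paired_pulse_ratio",
    "analyze_train",
]

BASELINE_S = 0.002  # pre-stimulus baseline window, 2 ms


@dataclass
class RRPEstimate:
    """Back-extrapolated cumulative-EPSC fit."""

    fit_slope: float          # nA per stimulus (steady-state replenishment)
    fit_intercept_nA: float   # cumulative EPSC at stimulus index 0
    rrp_quanta: float         # intercept / quantal size
    n_fit: int
    flags: list[str] = field(default_factory=list)


@dataclass
class PTrainResult:
    """Fraction of the total RRP released by the first stimulus."""

    value: float
    flag: str | None = None   # None | "clipped" | "undefined"


@dataclass
class DecayFit:
    """Single-phase decay fit a(i) = plateau + span * exp(-(i - 2)/tau)."""

    decay_constant: float     # tau, in stimuli
    plateau: float
    span: float
    flag: str | None = None   # None | "no-decay" | "no-convergence"


@dataclass
class TrainResult:
    """Full analysis of one (averaged) 60-Hz train."""

    amplitudes: np.ndarray
    cumulative: np.ndarray
    rrp: RRPEstimate
    ptrain: PTrainResult
    decay: DecayFit
    n_trains: int = 1

    def summary(self) -> str:
        lines = [
            "Train analysis",
            f"  stimuli analysed : {self.amplitudes.size}  (trains averaged: {self.n_trains})",
            f"  EPSC 1           : {self.amplitudes[0]:.4g} nA",
            f"  cumulative EPSC  : {self.cumulative[-1]:.4g} nA",
            f"  fit slope        : {self.rrp.fit_slope:.4g} nA/stimulus",
            f"  intercept (RRP)  : {self.rrp.fit_intercept_nA:.4g} nA",
            f"  RRP (quanta)     : {self.rrp.rrp_quanta:.4g}",
            f"  P_train          : {self.ptrain.value:.4g}"
            + (f"  [{self.ptrain.flag}]" if self.ptrain.flag else ""),
            f"  decay constant   : {self.decay.decay_constant:.4g} stimuli"
            + (f"  [{self.decay.flag}]" if self.decay.flag else ""),
        ]
        return "\n".join(lines)


def _polarity_for(trace: Trace) -> str:
    return "down" if trace.channel == "current_nA" else "up"


def train_amplitudes(sweep: Trace, stimulus_times: Sequence[float]) -> np.ndarray:
    """Per-stimulus amplitudes: |peak - pre-stimulus baseline| for each EPSC.

    For stimulus i the baseline is the mean over [t_i - 2 ms, t_i) and the
    peak is the extremum in (t_i, t_{i+1}); the last stimulus's search window
    extends one inter-stimulus interval past its onset.  Amplitudes are
    magnitudes, invariant to a constant offset on the whole sweep.
    """
    st = np.asarray(stimulus_times, dtype=float)
    if st.size < 1:
        raise ParameterError("need at least one stimulus time")
    if st.size > 1 and np.min(np.diff(st)) < BASELINE_S:
        raise ParameterError("stimuli closer than the 2-ms baseline window overlap")
    isi = float(np.median(np.diff(st))) if st.size > 1 else 0.05
    pol = _polarity_for(sweep)
    amps = np.zeros(st.size)
    for i, t_i in enumerate(st):
        t_end = st[i + 1] if i + 1 < st.size else t_i + isi
        base = baseline_mean(sweep, (t_i - BASELINE_S, t_i))
        seg = sweep.slice(t_i + sweep.dt / 2, t_end)
        if seg.size == 0:
            raise ParameterError(f"empty search window after stimulus {i}")
        ext = float(np.min(seg)) if pol == "down" else float(np.max(seg))
        amps[i] = abs(ext - base)
    return amps


def estimate_rrp(amplitudes: Sequence[float], quantal_size: float,
                 n_fit: int = 10) -> RRPEstimate:
    """Back-extrapolate the cumulative EPSC to stimulus index 0.

    OLS on (stimulus index, cumulative amplitude) over the last ``n_fit``
    points; the intercept at index 0 is the cumulative EPSC of the initial
    pool and ``rrp_quanta`` is that intercept divided by ``quantal_size``
    (the same-cell mean mEPSC amplitude).  A negative intercept is flagged.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if quantal_size <= 0:
        raise ParameterError("quantal_size must be > 0")
    if not (2 <= n_fit <= amps.size):
        raise ParameterError(f"n_fit must lie in [2, {amps.size}]")
    cum = np.cumsum(amps)
    idx = np.arange(1, amps.size + 1, dtype=float)
    slope, intercept = np.polyfit(idx[-n_fit:], cum[-n_fit:], 1)
    flags = []
    if intercept < 0:
        flags.append("negative_intercept")
    return RRPEstimate(float(slope), float(intercept),
                       float(intercept / quantal_size), n_fit, flags)


def p_train(amplitudes: Sequence[float], fit_intercept_nA: float) -> PTrainResult:
    """First-stimulus amplitude / back-extrapolated intercept.

    Values above 1 are reported clipped with a warning flag; a non-positive
    intercept yields an undefined (NaN) result, flagged rather than raised.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if fit_intercept_nA <= 0:
        warnings.warn("P_train undefined: non-positive back-extrapolated intercept")
        return PTrainResult(float("nan"), "undefined")
    v = float(amps[0] / fit_intercept_nA)
    if v > 1.0:
        warnings.warn(f"P_train = {v:.3g} > 1; reporting clipped value")
        return PTrainResult(1.0, "clipped")
    return PTrainResult(v)


def _decay_model(i: np.ndarray, plateau: float, span: float, tau: float) -> np.ndarray:
    return plateau + span * np.exp(-(i - 2.0) / tau)


def depression_decay_fit(amplitudes: Sequence[float],
                         first: int = 2, last: int = 10) -> DecayFit:
    """Single-phase decay fit to stimuli ``first``..``last`` (1-based).

    Fits a(i) = plateau + span * exp(-(i - first)/tau) by least squares and
    returns tau in stimulus units.  A non-positive fitted span means no
    depression ("no-decay" flag); non-convergence is flagged, not raised.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < last:
        raise ParameterError(f"need amplitudes up to stimulus {last}")
    i = np.arange(first, last + 1, dtype=float)
    y = amps[first - 1:last]
    span0 = y[0] - y[-1]
    if span0 <= 0 or np.allclose(y, y[0]):
        return DecayFit(float("nan"), float(np.mean(y)), 0.0, "no-decay")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _decay_model, i, y, p0=[y[-1], span0, 2.0],
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
                maxfev=10000)
    except (RuntimeError, ValueError):
        return DecayFit(float("nan"), float("nan"), float("nan"), "no-convergence")
    plateau, span, tau = (float(v) for v in popt)
    if span <= 0:
        return DecayFit(float("nan"), plateau, span, "no-decay")
    return DecayFit(tau, plateau, span, None)


def paired_pulse_ratio(sweep: Trace, stimulus_times: Sequence[float]) -> float:
    """Amplitude2 / amplitude1 under the train measurement rules.

    Returns NaN (with a warning) when the first amplitude is zero.
    """
    st = np.asarray(stimulus_times, dtype=float)
    if st.size != 2:
        raise ParameterError("paired-pulse analysis requires exactly two stimuli")
    a1, a2 = train_amplitudes(sweep, st)
    if a1 == 0:
        warnings.warn("paired-pulse ratio undefined: first amplitude is zero")
        return float("nan")
    return float(a2 / a1)


def analyze_train(sweepset: SweepSet, quantal_size: float,
                  n_fit: int = 10) -> TrainResult:
    """Average >= 1 train sweeps of a synapse and run the full train analysis.

    Per-stimulus amplitudes are measured on each sweep and averaged across
    sweeps (the standard protocol records at least five trains per synapse)
    before the cumulative fit, P_train and decay fit.
    """
    per_sweep = np.array([train_amplitudes(sw, st)
                          for sw, st in zip(sweepset.sweeps, sweepset.stimulus_times)])
    amps = per_sweep.mean(axis=0)
    rrp = estimate_rrp(amps, quantal_size, n_fit=n_fit)
    pt = p_train(amps, rrp.fit_intercept_nA)
    decay = depression_decay_fit(amps) if amps.size >= 10 else DecayFit(
        float("nan"), float("nan"), float("nan"), "too-few-stimuli")
    return TrainResult(amps, np.cumsum(amps), rrp, pt, decay,
                       n_trains=sweepset.n_sweeps)
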