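"""Core data containers, trace file I/O and generic signal utilities.

Unit conventions, fixed package-wide: time in seconds, membrane potential in
mV, membrane current in nA, fluorescence in arbitrary units (a.u.).  All
amplitudes elsewhere in the package are reported as magnitudes, so an inward
(downward) synaptic current of -3.2 nA has amplitude 3.2.

Traces live on disk as two-column CSV (``time_s,value``) with a JSON sidecar
carrying the channel, label and optional recording metadata; sweep
collections are described by a JSON manifest.  The text dialect is chosen for
auditability and is lossless at 12 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ParameterError, TraceFormatError, TraceDataError

__all__ = [
    "Trace",
    "SweepSet",
    "RecordingMeta",
    "CHANNELS",
    "read_trace",
    "write_trace",
    "read_sweepset",
    "write_sweepset",
    "lowpass",
    "baseline_mean",
    "peak_amplitude",
]

#: Allowed channel identifiers and their physical units.
CHANNELS = ("voltage_mV", "current_nA", "fluorescence_au")

#: Permitted stimulation protocols for SweepSet.
PROTOCOLS = ("single_AP", "train_60Hz_30", "paired_pulse", "arch_spot", "ca_linescan")

_TIME_UNIFORMITY_TOL = 1e-6  # seconds; max deviation from a uniform grid


@dataclass
class Trace:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    samples : array-like
        Sample values in channel units (mV, nA or a.u.).
    dt : float
        Sampling interval in seconds; must be positive.
    t0 : float
        Time of the first sample, seconds.
    channel : str
        One of :data:`CHANNELS`.
    label : str
        Free-text label (genotype, bouton id, ...).
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    channel: str = "voltage_mV"
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("trace requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise TraceDataError("trace contains non-finite samples")
        if not (self.dt > 0):
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.channel not in CHANNELS:
            raise ParameterError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        return self.dt * self.samples.size

    @property
    def fs(self) -> float:
        """Sampling frequency, Hz."""
        return 1.0 / self.dt

    def with_samples(self, samples: np.ndarray, *, label: str | None = None) -> "Trace":
        """Copy of this trace with new samples on the same time grid."""
        return Trace(np.asarray(samples, dtype=float), self.dt, self.t0,
                     self.channel, self.label if label is None else label)

    def slice(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples whose timestamps lie in [t_start, t_end)."""
        t = self.times
        return self.samples[(t >= t_start) & (t < t_end)]


@dataclass
class RecordingMeta:
    """Experiment-level metadata attached to a recording."""

    genotype: str = ""
    ca_external_mM: float = 1.0
    vm_rest_mV: float = -70.0
    clamp_mode: str = "current_clamp"  # or "TEVC"
    temperature_note: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.ca_external_mM <= 10):
            raise ParameterError(
                f"ca_external_mM must lie in (0, 10], got {self.ca_external_mM}")
        if self.clamp_mode not in ("current_clamp", "TEVC"):
            raise ParameterError(f"unknown clamp_mode {self.clamp_mode!r}")


@dataclass
class SweepSet:
    """Stimulus-aligned collection of sweeps sharing a time grid.

    ``stimulus_times[i]`` holds the stimulus-onset times (seconds, strictly
    increasing) of sweep ``i``.  For the 60-Hz train protocol every sweep must
    carry exactly 30 onsets at ~16.67 ms spacing.
    """

    sweeps: list[Trace]
    stimulus_times: list[np.ndarray]
    protocol: str
    meta: RecordingMeta | None = None

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ParameterError("SweepSet requires at least one sweep")
        if self.protocol not in PROTOCOLS:
            raise ParameterError(f"unknown protocol {self.protocol!r}")
        if len(self.stimulus_times) != len(self.sweeps):
            raise ParameterError("one stimulus-time vector required per sweep")
        ref = self.sweeps[0]
        for sw in self.sweeps:
            if abs(sw.dt - ref.dt) > 1e-12 or sw.samples.size != ref.samples.size:
                raise ParameterError("all sweeps must share dt and length")
            if sw.channel != ref.channel:
                raise ParameterError("all sweeps must share a channel")
        self.stimulus_times = [np.asarray(st, dtype=float) for st in self.stimulus_times]
        for st in self.stimulus_times:
            if st.size and np.any(np.diff(st) <= 0):
                raise ParameterError("stimulus times must be strictly increasing")
            if self.protocol == "train_60Hz_30":
                if st.size != 30:
                    raise ParameterError("train_60Hz_30 requires exactly 30 stimulus times")
                if np.max(np.abs(np.diff(st) - 1.0 / 60.0)) > 1e-3:
                    raise ParameterError("train_60Hz_30 spacing must be ~16.67 ms")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


# ---------------------------------------------------------------------------
# File I/O

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: Trace, path: str | Path, *, meta: RecordingMeta | None = None) -> None:
    """Write ``trace`` as two-column CSV plus a JSON sidecar.

    The dialect is exactly what :func:`read_trace` accepts and round-trips
    values at 12 significant digits.
    """
    path = Path(path)
    t = trace.times
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{ti:.12g},{vi:.12g}\n")
    sidecar = {"channel": trace.channel, "label": trace.label, "dt": trace.dt, "t0": trace.t0}
    if meta is not None:
        sidecar["genotype"] = meta.genotype
        sidecar["ca_external_mM"] = meta.ca_external_mM
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_trace(path: str | Path) -> Trace:
    """Read a CSV trace written in the package dialect.

    dt is inferred from the median time step; a non-uniform time grid (beyond
    1e-6 s) or non-monotonic timestamps raise :class:`TraceDataError`, a
    missing sidecar raises :class:`TraceFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such trace file: {path}")
    side = _sidecar_path(path)
    if not side.exists():
        raise TraceFormatError(f"missing JSON sidecar for {path}")
    with open(side) as fh:
        sidecar = json.load(fh)
    if "channel" not in sidecar:
        raise TraceFormatError(f"sidecar {side} lacks required field 'channel'")
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise TraceFormatError(f"{path}: expected two-column CSV with >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise TraceDataError(f"{path}: time stamps are not strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > _TIME_UNIFORMITY_TOL:
        raise TraceDataError(f"{path}: time grid non-uniform beyond {_TIME_UNIFORMITY_TOL} s")
    return Trace(v, dt=dt, t0=float(t[0]),
                 channel=sidecar["channel"], label=sidecar.get("label", ""))


def write_sweepset(sweepset: SweepSet, directory: str | Path, *, stem: str = "sweep") -> Path:
    """Write every sweep as a trace CSV plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, sw in enumerate(sweepset.sweeps):
        name = f"{stem}_{i:03d}.csv"
        write_trace(sw, directory / name, meta=sweepset.meta)
        files.append(name)
    manifest = {
        "protocol": sweepset.protocol,
        "sweeps": files,
        "stimulus_times": [st.tolist() for st in sweepset.stimulus_times],
    }
    if sweepset.meta is not None:
        manifest["meta"] = asdict(sweepset.meta)
    mpath = directory / f"{stem}.manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def read_sweepset(manifest_path: str | Path) -> SweepSet:
    """Load a SweepSet from a manifest written by :func:`write_sweepset`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    sweeps = [read_trace(base / name) for name in manifest["sweeps"]]
    meta = RecordingMeta(**manifest["meta"]) if "meta" in manifest else None
    return SweepSet(sweeps,
                    [np.asarray(st, dtype=float) for st in manifest["stimulus_times"]],
                    manifest["protocol"], meta=meta)


# ---------------------------------------------------------------------------
# Signal utilities

def lowpass(trace: Trace, cutoff_hz: float) -> Trace:
    """Zero-phase 4-pole low-pass filter (2nd-order Butterworth, forward-backward).

    Output length equals input length and DC gain is 1.  Raises
    :class:`ParameterError` when the cutoff reaches the Nyquist frequency.
    """
    nyquist = 0.5 / trace.dt
    if not (0 < cutoff_hz < nyquist):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:g} Hz)")
    b, a = signal.butter(2, cutoff_hz / nyquist)
    out = signal.filtfilt(b, a, trace.samples)
    return trace.with_samples(out)


def baseline_mean(trace: Trace, window: tuple[float, float]) -> float:
    """Arithmetic mean of samples with timestamps in ``[t_start, t_end)``."""
    t_start, t_end = window
    if not (t_start < t_end):
        raise ParameterError(f"baseline window requires t_start < t_end, got {window}")
    seg = trace.slice(t_start, t_end)
    if seg.size == 0:
        raise ParameterError(f"baseline window {window} contains no samples")
    return float(np.mean(seg))


def peak_amplitude(trace: Trace,
                   search_window: tuple[float, float],
                   baseline_window: tuple[float, float],
                   polarity: str = "up") -> float:
    """|extremum − baseline| of a deflection, as a non-negative magnitude.

    ``polarity`` declares the deflection direction: EPSPs in current clamp go
    up, EPSCs in voltage clamp go down; the reported amplitude is positive
    either way and invariant to adding a constant to the whole trace.
    """
    if polarity not in ("up", "down"):
        raise ParameterError(f"polarity must be 'up' or 'down', got {polarity!r}")
    base = baseline_mean(trace, baseline_window)
    seg = trace.slice(*search_window)
    if seg.size == 0:
        raise ParameterError(f"search window {search_window} contains no samples")
    ext = float(np.max(seg)) if polarity == "up" else float(np.min(seg))
    return abs(ext - base)
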