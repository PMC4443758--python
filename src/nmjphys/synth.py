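"""Ground-truth simulators for every input the analysis pipelines consume.

Four generators emulate the experimental recordings this package analyses:

* evoked EPSC trains from a binomial vesicle-release model with pool
  depletion and continuous replenishment (the classical N, p, q quantal
  model under which cumulative-EPSC back-extrapolation is meaningful);
* spontaneous miniature-event records with Poisson timing and lognormal
  amplitudes, including the ~1.55x quantal-size scaling of vGlut
  overexpression;
* calcium line-scan ROI/background trace pairs with bleaching drift;
* Arch voltage-imaging sweeps carrying tissue-fluorescence photobleach,
  the early photocycle brightening, and a Gaussian AP-shaped transient.

Every generator is deterministic under its seed and emits, alongside the
traces, a ground-truth record against which pipeline outputs can be scored.
Release probability couples to external calcium through a power law
``p_eff = p_r * (ca / ca_ref) ** ca_exponent`` with exponent ~3, the
cooperativity regime of the fly NMJ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .quantal import RecordingSummary
from .trace import Trace, SweepSet, RecordingMeta

__all__ = [
    "ReleaseModelParams",
    "MiniTrainParams",
    "CaLinescanParams",
    "ArchTraceParams",
    "simulate_evoked_train",
    "simulate_mini_record",
    "simulate_ca_linescan",
    "simulate_arch_record",
    "simulate_cooperativity_dataset",
    "simulate_homeostasis_population",
]

_GAUSS_WHM = 2.0 * math.sqrt(2.0 * math.log(2.0))       # FWHM / sigma
_GAUSS_W10 = 2.0 * math.sqrt(2.0 * math.log(10.0))      # width at 10% / sigma


# ---------------------------------------------------------------------------
# Parameter dataclasses

@dataclass
class ReleaseModelParams:
    """Binomial release model: N vesicles, per-stimulus release probability p.

    ``p_r`` applies at external calcium ``ca_ref_mM``; at other calcium
    concentrations it is scaled by ``(ca / ca_ref) ** ca_exponent``.
    Quantal sizes are lognormal with mean ``q_mean`` and coefficient of
    variation ``q_cv``; ``replenish_rate`` refills the pool between stimuli
    (vesicles per second, capped at ``n_pool``).
    """

    n_pool: int = 600
    p_r: float = 0.4
    q_mean: float = 0.06          # nA; ~mEPSC amplitude at 3 mM calcium
    q_cv: float = 0.3
    replenish_rate: float = 0.0
    ca_exponent: float = 3.0
    ca_ref_mM: float = 3.0
    noise_sd: float = 0.0         # additive recording noise, channel units

    def __post_init__(self) -> None:
        if self.n_pool <= 0:
            raise ParameterError("n_pool must be a positive integer")
        if not (0 < self.p_r <= 1):
            raise ParameterError("p_r must lie in (0, 1]")
        if self.q_mean <= 0 or self.q_cv < 0:
            raise ParameterError("q_mean must be > 0 and q_cv >= 0")
        if self.replenish_rate < 0 or self.noise_sd < 0:
            raise ParameterError("replenish_rate and noise_sd must be >= 0")
        if self.ca_exponent <= 0 or self.ca_ref_mM <= 0:
            raise ParameterError("ca_exponent and ca_ref_mM must be > 0")

    def effective_p(self, ca_mM: float, *, clip: bool = False) -> float:
        """Release probability at ``ca_mM`` under the power-law coupling."""
        p = self.p_r * (ca_mM / self.ca_ref_mM) ** self.ca_exponent
        if p > 1.0:
            if not clip:
                raise ParameterError(
                    f"effective p_r = {p:.3g} > 1 at {ca_mM} mM calcium; "
                    "pass clip=True to clip to 1")
            p = 1.0
        if p <= 0:
            raise ParameterError("effective p_r must be positive")
        return p


@dataclass
class MiniTrainParams:
    """Spontaneous miniature-event record parameters.

    ``vglut_scale`` multiplies the event amplitude only (1.0 wild type,
    ~1.55 for vGlut overexpression); event rate is independent of it.
    """

    rate_hz: float = 2.0
    amp_mean: float = 0.9         # mV, wild-type mEPSP scale
    amp_cv: float = 0.3
    vglut_scale: float = 1.0
    rise_s: float = 0.002
    decay_s: float = 0.008
    noise_sd: float = 0.05        # mV
    fs_hz: float = 10000.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.amp_mean <= 0 or self.vglut_scale <= 0:
            raise ParameterError("rate_hz, amp_mean and vglut_scale must be > 0")
        if self.amp_cv < 0 or self.noise_sd < 0:
            raise ParameterError("amp_cv and noise_sd must be >= 0")
        if self.rise_s <= 0 or self.decay_s <= self.rise_s:
            raise ParameterError("require 0 < rise_s < decay_s")


@dataclass
class CaLinescanParams:
    """Calcium line-scan generator: ROI/background pairs at 313 Hz.

    The ROI fluorescence obeys
    ``F(t) = f_background + (f_baseline - f_background) * (1 + dff(t)) * bleach(t)``
    with ``dff`` zero before the stimulus and peaking at ``dff_peak``;
    ``drift_frac`` is the fractional change of the resting component across
    the record (negative = bleaching).
    """

    f_baseline: float = 400.0
    f_background: float = 60.0
    dff_peak: float = 0.35
    decay_tau_s: float = 0.15
    drift_frac: float = 0.0
    fs_hz: float = 313.0
    n_scans: int = 10
    noise_sd: float = 3.0         # a.u.
    stim_time_s: float = 1.5
    duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.f_baseline <= 0 or self.f_background < 0:
            raise ParameterError("f_baseline must be > 0 and f_background >= 0")
        if self.f_baseline <= self.f_background:
            raise ParameterError("f_baseline must exceed f_background")
        if self.dff_peak < 0 or self.decay_tau_s <= 0 or self.noise_sd < 0:
            raise ParameterError("dff_peak/noise_sd must be >= 0, decay_tau_s > 0")
        if not (0.3 <= self.stim_time_s < self.duration_s):
            raise ParameterError("stimulus must fall >= 0.3 s into the record")


@dataclass
class ArchTraceParams:
    """Arch voltage-imaging sweep generator at 4 kHz.

    Each sweep is tissue photobleach (single exponential) + the rapid Arch
    photocycle brightening over the first ~10 ms + a Gaussian AP-shaped
    voltage transient shortly after the stimulus, which follows 60 ms of
    baseline acquisition.  The AP's full width at the 10%-of-peak threshold
    is fixed by its WHM for a Gaussian (factor sqrt(ln10/ln2) ~ 1.823), so
    ``ap_width_ms`` is derived rather than free.
    """

    tissue_amp: float = 300.0
    tissue_tau: float = 0.05      # s; fast enough that the 45-ms fit window spans ~1 tau
    photocycle_rise_ms: float = 10.0
    photocycle_amp: float = 40.0
    ap_peak: float = 60.0
    ap_whm_ms: float = 1.2
    ap_delay_ms: float = 2.0      # stimulus onset -> AP peak
    stim_time_s: float = 0.060
    duration_s: float = 0.200
    fs_hz: float = 4000.0
    extra_ap_prob: float = 0.0
    noise_sd: float = 1.0
    baseline_offset: float = 150.0

    def __post_init__(self) -> None:
        if self.ap_whm_ms <= 0 or self.tissue_tau <= 0:
            raise ParameterError("ap_whm_ms and tissue_tau must be > 0")
        if not (0 <= self.extra_ap_prob < 1):
            raise ParameterError("extra_ap_prob must lie in [0, 1)")
        if self.noise_sd < 0 or self.ap_peak < 0:
            raise ParameterError("noise_sd and ap_peak must be >= 0")
        if self.stim_time_s < 0.015:
            raise ParameterError("stimulus must follow the baseline acquisition window")

    @property
    def ap_width_ms(self) -> float:
        """Full width at 10% of peak implied by the Gaussian shape."""
        return self.ap_whm_ms * _GAUSS_W10 / _GAUSS_WHM


# ---------------------------------------------------------------------------
# Kinetic templates

def _event_template(dt: float, rise_s: float, decay_s: float, support_s: float) -> np.ndarray:
    """Difference-of-exponentials event shape, tapered to exact zero at the
    end of its support and normalized to a sampled peak of exactly 1."""
    t = np.arange(0.0, support_s, dt)
    g = (np.exp(-t / decay_s) - np.exp(-t / rise_s)) * np.cos(np.pi * t / (2 * support_s)) ** 2
    g[g < 0] = 0.0
    return g / g.max()


def _stimulus_schedule(protocol: str, interval_s: float | None, t_first: float) -> np.ndarray:
    if protocol == "train_60Hz_30":
        return t_first + np.arange(30) / 60.0
    if protocol == "single_AP":
        return np.array([t_first])
    if protocol == "paired_pulse":
        if interval_s is None or interval_s <= 0:
            raise ParameterError("paired_pulse requires a positive interval_s")
        return np.array([t_first, t_first + interval_s])
    raise ParameterError(f"unknown evoked protocol {protocol!r}")


def _unit_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal draws with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


# ---------------------------------------------------------------------------
# Evoked trains

def simulate_evoked_train(params: ReleaseModelParams,
                          protocol: str = "train_60Hz_30",
                          ca_mM: float | None = None,
                          seed: int = 0,
                          *,
                          n_sweeps: int = 5,
                          interval_s: float | None = None,
                          clip: bool = False,
                          fs_hz: float = 10000.0,
                          t_first: float = 0.05) -> tuple[SweepSet, dict]:
    """Simulate evoked EPSC sweeps from the binomial depletion model.

    Per stimulus the released count is Binomial(current pool, effective p);
    the pool is decremented by the released count and replenished at
    ``replenish_rate`` vesicles/s between stimuli (capped at ``n_pool``).
    The EPSC amplitude is the sum of that stimulus's quantal sizes, rendered
    as a downward current deflection plus optional Gaussian noise.

    Returns the SweepSet plus a ground-truth dict with the exact per-stimulus
    released counts, amplitudes, pool trajectory and effective p.
    """
    if ca_mM is None:
        ca_mM = params.ca_ref_mM
    p_eff = params.effective_p(ca_mM, clip=clip)
    if n_sweeps < 1:
        raise ParameterError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_hz

    stim = _stimulus_schedule(protocol, interval_s, t_first)
    stim = np.round(stim / dt) * dt                      # snap onsets to the grid
    min_isi = float(np.min(np.diff(stim))) if stim.size > 1 else 0.05
    support = min(0.012, 0.8 * min_isi) if stim.size > 1 else 0.012
    template = _event_template(dt, rise_s=0.0005, decay_s=0.004, support_s=support)
    duration = stim[-1] + 0.06
    n_samp = int(round(duration / dt))

    sweeps, truth_counts, truth_amps, truth_pools = [], [], [], []
    for _ in range(n_sweeps):
        pool = float(params.n_pool)
        counts = np.zeros(stim.size, dtype=int)
        amps = np.zeros(stim.size)
        pools = np.zeros(stim.size)
        prev_t = None
        for i, t_i in enumerate(stim):
            if prev_t is not None and params.replenish_rate > 0:
                pool = min(float(params.n_pool), pool + params.replenish_rate * (t_i - prev_t))
            pools[i] = pool
            k = int(rng.binomial(int(math.floor(pool)), p_eff)) if pool >= 1 else 0
            quanta = params.q_mean * _unit_lognormal(rng, params.q_cv, k)
            counts[i] = k
            amps[i] = float(np.sum(quanta))
            pool -= k
            prev_t = t_i
        samples = np.zeros(n_samp)
        for t_i, a in zip(stim, amps):
            j = int(round(t_i / dt))
            seg = template[: max(0, n_samp - j)]
            samples[j:j + seg.size] += -a * seg          # EPSC: downward current
        if params.noise_sd > 0:
            samples = samples + rng.normal(0.0, params.noise_sd, n_samp)
        sweeps.append(Trace(samples, dt=dt, channel="current_nA", label="evoked"))
        truth_counts.append(counts)
        truth_amps.append(amps)
        truth_pools.append(pools)

    meta = RecordingMeta(ca_external_mM=ca_mM, clamp_mode="TEVC")
    sweepset = SweepSet(sweeps, [stim.copy() for _ in range(n_sweeps)], protocol, meta=meta)
    truth = {
        "released": np.array(truth_counts),
        "amplitudes": np.array(truth_amps),
        "pool_before_stimulus": np.array(truth_pools),
        "p_eff": p_eff,
        "q_mean": params.q_mean,
        "stimulus_times": stim,
    }
    return sweepset, truth


# ---------------------------------------------------------------------------
# Miniature records

def simulate_mini_record(params: MiniTrainParams,
                         duration_s: float,
                         seed: int = 0) -> tuple[Trace, list[dict]]:
    """Simulate a spontaneous miniature-EPSP record.

    Event times are a Poisson process at ``rate_hz``; amplitudes are
    lognormal with mean ``amp_mean * vglut_scale``.  Times and the unit
    amplitude draws are generated before scaling, so two records differing
    only in ``vglut_scale`` share event times exactly and differ in
    amplitude by exactly that factor.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.fs_hz
    n_samp = int(round(duration_s / dt))
    n_ev = int(rng.poisson(params.rate_hz * duration_s))
    t_ev = np.sort(rng.uniform(0.0, duration_s, n_ev))
    t_ev = np.round(t_ev / dt) * dt
    amps = params.amp_mean * params.vglut_scale * _unit_lognormal(rng, params.amp_cv, n_ev)

    template = _event_template(dt, params.rise_s, params.decay_s,
                               support_s=6.0 * params.decay_s)
    samples = np.zeros(n_samp)
    events = []
    for t_i, a in zip(t_ev, amps):
        j = int(round(t_i / dt))
        if j >= n_samp:
            continue
        seg = template[: n_samp - j]
        samples[j:j + seg.size] += a * seg               # mEPSP: upward voltage
        t_peak = t_i + np.argmax(template) * dt
        events.append({"t_onset": float(t_i), "t_peak": float(t_peak), "amplitude": float(a)})
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, n_samp)
    trace = Trace(samples, dt=dt, channel="voltage_mV", label="spontaneous")
    return trace, events


# ---------------------------------------------------------------------------
# Calcium line scans

def simulate_ca_linescan(params: CaLinescanParams,
                         seed: int = 0) -> tuple[list[Trace], list[Trace], dict]:
    """Simulate ``n_scans`` ROI/background line-scan trace pairs.

    The transient rises instantaneously at the stimulus to ``dff_peak`` and
    decays exponentially with ``decay_tau_s``; bleaching multiplies the
    resting (indicator) component linearly by ``1 + drift_frac * t/T``.
    """
    if not (1 <= params.n_scans):
        raise ParameterError("n_scans must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.fs_hz
    n_samp = int(round(params.duration_s / dt))
    t = dt * np.arange(n_samp)
    stim = round(params.stim_time_s / dt) * dt           # snap onset to the grid
    dff = np.where(t >= stim, params.dff_peak * np.exp(-(t - stim) / params.decay_tau_s), 0.0)
    bleach = 1.0 + params.drift_frac * t / params.duration_s
    clean_roi = params.f_background + (params.f_baseline - params.f_background) * (1.0 + dff) * bleach

    rois, backgrounds = [], []
    for _ in range(params.n_scans):
        r = clean_roi + (rng.normal(0.0, params.noise_sd, n_samp) if params.noise_sd > 0 else 0.0)
        b = np.full(n_samp, params.f_background) + (
            rng.normal(0.0, params.noise_sd, n_samp) if params.noise_sd > 0 else 0.0)
        rois.append(Trace(r, dt=dt, channel="fluorescence_au", label="roi"))
        backgrounds.append(Trace(b, dt=dt, channel="fluorescence_au", label="background"))
    truth = {
        "dff_peak": params.dff_peak,
        "decay_tau_s": params.decay_tau_s,
        "stim_time_s": stim,
        "dff": dff,
        "drift_frac": params.drift_frac,
    }
    return rois, backgrounds, truth


# ---------------------------------------------------------------------------
# Arch voltage imaging

def simulate_arch_record(params: ArchTraceParams,
                         n_events: int,
                         seed: int = 0) -> tuple[SweepSet, dict]:
    """Simulate ``n_events`` Arch spot-imaging sweeps.

    Each sweep = tissue photobleach exponential + photocycle brightening
    (settling within ~10 ms) + Gaussian AP transient after the stimulus +
    noise.  With probability ``extra_ap_prob`` a sweep carries a second,
    off-schedule AP at a uniform random offset >= 20 ms after the stimulus,
    exercising the extra-AP rejection rule downstream.
    """
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.fs_hz
    n_samp = int(round(params.duration_s / dt))
    t = dt * np.arange(n_samp)

    sigma_s = params.ap_whm_ms / 1000.0 / _GAUSS_WHM
    ap_center = params.stim_time_s + params.ap_delay_ms / 1000.0
    ap_clean = params.ap_peak * np.exp(-0.5 * ((t - ap_center) / sigma_s) ** 2)

    pc_tau = params.photocycle_rise_ms / 1000.0 / 5.0    # settles within the rise window
    base = (params.baseline_offset
            + params.tissue_amp * np.exp(-t / params.tissue_tau)
            + params.photocycle_amp * (1.0 - np.exp(-t / pc_tau)))

    sweeps, has_extra = [], []
    lo = params.stim_time_s + 0.020
    hi = params.duration_s - 0.020
    for _ in range(n_events):
        y = base + ap_clean
        extra = bool(rng.random() < params.extra_ap_prob)
        if extra:
            t_x = rng.uniform(lo, hi)
            y = y + params.ap_peak * np.exp(-0.5 * ((t - t_x) / sigma_s) ** 2)
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, n_samp)
        sweeps.append(Trace(y, dt=dt, channel="fluorescence_au", label="arch"))
        has_extra.append(extra)

    sweepset = SweepSet(sweeps, [np.array([params.stim_time_s])] * n_events, "arch_spot")
    truth = {
        "ap_waveform": Trace(ap_clean, dt=dt, channel="fluorescence_au", label="ap_truth"),
        "ap_whm_ms": params.ap_whm_ms,
        "ap_width_ms": params.ap_width_ms,
        "ap_peak_time_s": ap_center,
        "has_extra_ap": np.array(has_extra),
    }
    return sweepset, truth


# ---------------------------------------------------------------------------
# Population-level generators

def simulate_cooperativity_dataset(params: ReleaseModelParams,
                                   ca_levels_mM: Sequence[float],
                                   sweeps_per_level: int,
                                   seed: int = 0) -> pd.DataFrame:
    """Mean single-AP quantal content (with SEM) at each calcium level.

    Runs :func:`simulate_evoked_train` with the single-AP protocol per level;
    quantal content per sweep is the evoked amplitude divided by the model's
    mean quantal size.
    """
    ca_levels_mM = list(ca_levels_mM)
    if len(ca_levels_mM) < 3:
        raise ParameterError("need at least 3 calcium levels")
    if sweeps_per_level < 1:
        raise ParameterError("sweeps_per_level must be >= 1")
    for ca in ca_levels_mM:
        params.effective_p(ca)                            # raises if p_eff > 1
    rows = []
    rng = np.random.default_rng(seed)
    for ca in ca_levels_mM:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        _, truth = simulate_evoked_train(params, "single_AP", ca, sub_seed,
                                         n_sweeps=sweeps_per_level)
        qc = truth["amplitudes"][:, 0] / params.q_mean
        sem = float(np.std(qc, ddof=1) / math.sqrt(qc.size)) if qc.size > 1 else float("nan")
        rows.append({"ca_mM": ca, "quantal_content": float(np.mean(qc)),
                     "sem": sem, "n_sweeps": qc.size})
    return pd.DataFrame(rows)


def simulate_homeostasis_population(setpoint_epsp_mV: float,
                                    mepsp_values_mV: Sequence[float],
                                    noise_cv: float = 0.0,
                                    seed: int = 0) -> list[RecordingSummary]:
    """Synthetic per-NMJ recordings under a perfect homeostatic set-point.

    For each mEPSP amplitude ``m`` the quantal content is
    ``setpoint / m`` perturbed by multiplicative lognormal noise, so the
    evoked EPSP is held at the set-point (up to noise) across an
    order-of-magnitude range of quantal sizes.
    """
    mepsp_values_mV = list(mepsp_values_mV)
    if setpoint_epsp_mV <= 0:
        raise ParameterError("setpoint_epsp_mV must be > 0")
    if not mepsp_values_mV:
        raise ParameterError("mepsp_values_mV must be non-empty")
    if any(m <= 0 for m in mepsp_values_mV):
        raise ParameterError("all mEPSP values must be > 0")
    rng = np.random.default_rng(seed)
    factors = _unit_lognormal(rng, noise_cv, len(mepsp_values_mV))
    out = []
    for m, f in zip(mepsp_values_mV, factors):
        qc = setpoint_epsp_mV / m * f
        out.append(RecordingSummary(
            mepsp_mean=m, mepsp_n=100, epsp_mean=qc * m, epsp_n=30,
            quantal_content=qc, vm_rest_mV=-70.0, accepted=True))
    return out
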