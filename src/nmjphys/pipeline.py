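"""End-to-end orchestration: from a directory of trace manifests (real or
simulated) to machine-readable per-recording results and a study summary.

Each analysis stage is dispatched on the manifest's ``protocol`` field.
Outputs are deterministic under a fixed seed and configuration: JSON is
written with sorted keys so re-runs are byte-identical.  A failed stage
leaves a ``<stem>.failed`` marker beside its partial outputs and the run
exits nonzero, but other stages still complete.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import archimg, calcium, quantal, synth, trains
from .errors import PipelineError, ParameterError
from .trace import Trace, read_trace, read_sweepset, write_trace, write_sweepset

__all__ = ["RunConfig", "run_pipeline", "simulate_dataset"]

log = logging.getLogger("nmjphys")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    quantal_size: float = 1.0       # fallback divisor (nA) when a manifest has none
    n_fit: int = 10
    genotype_labels: list[str] = field(default_factory=list)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _dump(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Per-protocol stages

def _stage_train(manifest: dict, mpath: Path, cfg: RunConfig) -> dict:
    ss = read_sweepset(mpath)
    q = float(manifest.get("quantal_size", cfg.quantal_size))
    res = trains.analyze_train(ss, q, n_fit=cfg.n_fit)
    return {
        "protocol": ss.protocol,
        "n_trains": res.n_trains,
        "amplitudes_nA": res.amplitudes,
        "cumulative_nA": res.cumulative,
        "fit_slope": res.rrp.fit_slope,
        "fit_intercept_nA": res.rrp.fit_intercept_nA,
        "rrp_quanta": res.rrp.rrp_quanta,
        "p_train": res.ptrain.value,
        "p_train_flag": res.ptrain.flag,
        "decay_constant": res.decay.decay_constant,
        "decay_flag": res.decay.flag,
        "quantal_size": q,
    }


def _stage_paired_pulse(manifest: dict, mpath: Path, cfg: RunConfig) -> dict:
    ss = read_sweepset(mpath)
    ratios = [trains.paired_pulse_ratio(sw, st)
              for sw, st in zip(ss.sweeps, ss.stimulus_times)]
    ratios = np.asarray(ratios)
    return {
        "protocol": ss.protocol,
        "ratios": ratios,
        "mean_ppr": float(np.nanmean(ratios)),
        "n_sweeps": ss.n_sweeps,
    }


def _stage_single_ap(manifest: dict, mpath: Path, cfg: RunConfig) -> dict:
    ss = read_sweepset(mpath)
    amps = np.array([trains.train_amplitudes(sw, st)[0]
                     for sw, st in zip(ss.sweeps, ss.stimulus_times)])
    q = float(manifest.get("quantal_size", cfg.quantal_size))
    return {
        "protocol": ss.protocol,
        "mean_amplitude": float(np.mean(amps)),
        "quantal_content": float(np.mean(amps) / q),
        "n_sweeps": ss.n_sweeps,
        "quantal_size": q,
    }


def _stage_spontaneous(manifest: dict, mpath: Path, cfg: RunConfig) -> dict:
    trace = read_trace(mpath.parent / manifest["trace"])
    events = quantal.detect_minis(trace)
    st = quantal.mini_stats(events, trace.duration)
    return {
        "protocol": "spontaneous",
        "n_events": st.n_events,
        "mepsp_mean": st.amp_mean,
        "mepsp_sem": st.amp_sem,
        "frequency_hz": st.frequency_hz,
        "flags": st.flags,
    }


def _stage_ca_linescan(manifest: dict, mpath: Path, cfg: RunConfig) -> dict:
    base = mpath.parent
    stim = float(manifest["stim_time_s"])
    rois = [read_trace(base / f) for f in manifest["rois"]]
    bgs = [read_trace(base / f) for f in manifest["backgrounds"]]
    qcs = [calcium.imaging_qc(r, stim) for r in rois]
    kept = [(r, b) for (r, b, q) in zip(rois, bgs, qcs) if not q.excluded]
    if not kept:
        raise PipelineError("all line scans excluded by imaging QC")
    dffs = [calcium.dff(r, b, stim) for r, b in kept]
    avg = calcium.average_transients(dffs, stim)
    return {
        "protocol": "ca_linescan",
        "peak_dff": avg.peak_dff,
        "n_scans_averaged": avg.n_scans_averaged,
        "n_scans_excluded": len(rois) - len(kept),
        "exclusion_reasons": [q.reason for q in qcs if q.excluded],
        "flags": avg.flags,
    }


def _stage_arch(manifest: dict, mpath: Path, cfg: RunConfig) -> dict:
    ss = read_sweepset(mpath)
    stim = float(ss.stimulus_times[0][0])
    residuals = [archimg.subtract_photobleach(sw, stim) for sw in ss.sweeps]
    accepted = archimg.reject_extra_ap(residuals, stim)
    ap = archimg.average_ap(accepted)
    return {
        "protocol": "arch_spot",
        "full_width_ms": ap.full_width_ms,
        "whm_ms": ap.whm_ms,
        "peak_time_s": ap.peak_time_s,
        "n_sweeps_accepted": ap.n_sweeps,
        "n_sweeps_rejected": len(residuals) - len(accepted),
    }


_STAGES = {
    "train_60Hz_30": _stage_train,
    "paired_pulse": _stage_paired_pulse,
    "single_AP": _stage_single_ap,
    "spontaneous": _stage_spontaneous,
    "ca_linescan": _stage_ca_linescan,
    "arch_spot": _stage_arch,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run every manifest in ``config.input_dir`` through its stage.

    Writes one ``<stem>.result.json`` per manifest plus ``summary.json``
    into ``config.output_dir``.  Raises :class:`PipelineError` (after
    preserving partial outputs and ``.failed`` markers) if any stage failed.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests = sorted(in_dir.glob("**/*.manifest.json"))
    if not manifests:
        raise PipelineError(f"no manifests found under {in_dir}")

    summary: dict[str, Any] = {"config": asdict(config), "recordings": {}, "failed": {}}
    for mpath in manifests:
        stem = mpath.name.replace(".manifest.json", "")
        with open(mpath) as fh:
            manifest = json.load(fh)
        protocol = manifest.get("protocol")
        stage = _STAGES.get(protocol)
        try:
            if stage is None:
                raise PipelineError(f"no stage for protocol {protocol!r}")
            log.info("stage %-14s %s", protocol, stem)
            result = stage(manifest, mpath, config)
            _dump(result, out_dir / f"{stem}.result.json")
            summary["recordings"][stem] = result
        except Exception as err:  # noqa: BLE001 — stage isolation is the contract
            log.error("stage failed for %s: %s", stem, err)
            (out_dir / f"{stem}.failed").write_text(f"{type(err).__name__}: {err}\n")
            summary["failed"][stem] = str(err)
    _dump(summary, out_dir / "summary.json")
    if summary["failed"]:
        raise PipelineError(f"{len(summary['failed'])} stage(s) failed; see summary.json")
    return summary


# ---------------------------------------------------------------------------
# Simulation -> files

def simulate_dataset(kind: str, out_dir: str | Path, seed: int = 0,
                     params: dict | None = None) -> Path:
    """Generate a synthetic dataset on disk in the dialect the pipeline reads.

    ``kind`` is one of ``train``, ``paired_pulse``, ``minis``, ``calcium``,
    ``arch``.  Returns the directory written; a ``ground_truth.json``
    records the generator's exact outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dict(params or {})
    truth_out: dict[str, Any] = {"kind": kind, "seed": seed}

    if kind in ("train", "paired_pulse"):
        interval = float(params.pop("interval_s", 0.05))
        rp = synth.ReleaseModelParams(**params)
        protocol = "train_60Hz_30" if kind == "train" else "paired_pulse"
        ss, truth = synth.simulate_evoked_train(
            rp, protocol, seed=seed, interval_s=interval if kind == "paired_pulse" else None)
        mpath = write_sweepset(ss, out_dir, stem=kind)
        with open(mpath) as fh:
            manifest = json.load(fh)
        manifest["quantal_size"] = rp.q_mean
        _dump(manifest, mpath)
        truth_out.update({k: v for k, v in truth.items()})
    elif kind == "minis":
        duration = float(params.pop("duration_s", 60.0))
        mp = synth.MiniTrainParams(**params)
        trace, events = synth.simulate_mini_record(mp, duration, seed=seed)
        write_trace(trace, out_dir / "minis.csv")
        _dump({"protocol": "spontaneous", "trace": "minis.csv"},
              out_dir / "minis.manifest.json")
        truth_out["events"] = events
    elif kind == "calcium":
        cp = synth.CaLinescanParams(**params)
        rois, bgs, truth = synth.simulate_ca_linescan(cp, seed=seed)
        roi_files, bg_files = [], []
        for i, (r, b) in enumerate(zip(rois, bgs)):
            rf, bf = f"roi_{i:02d}.csv", f"bg_{i:02d}.csv"
            write_trace(r, out_dir / rf)
            write_trace(b, out_dir / bf)
            roi_files.append(rf)
            bg_files.append(bf)
        _dump({"protocol": "ca_linescan", "rois": roi_files, "backgrounds": bg_files,
               "stim_time_s": truth["stim_time_s"]}, out_dir / "calcium.manifest.json")
        truth_out.update({k: v for k, v in truth.items() if k != "dff"})
    elif kind == "arch":
        n_events = int(params.pop("n_events", 30))
        ap = synth.ArchTraceParams(**params)
        ss, truth = synth.simulate_arch_record(ap, n_events, seed=seed)
        write_sweepset(ss, out_dir, stem="arch")
        truth_out.update({k: v for k, v in truth.items() if not isinstance(v, Trace)})
    else:
        raise ParameterError(f"unknown simulation kind {kind!r}")

    _dump(truth_out, out_dir / "ground_truth.json")
    return out_dir
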