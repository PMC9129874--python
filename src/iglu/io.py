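"""File formats, run manifests and the end-to-end experiment runner.

Movies travel as multi-page TIFF (frames-first, float32) with a JSON sidecar
carrying the acquisition metadata (``dt`` seconds per frame, ``pixel_size``
µm per pixel); traces, event tables, summaries and pair-correlation profiles
are plain CSV.  Every experiment output directory contains exactly one
``manifest.json`` snapshotting the configuration, the seed, the package
version and the SHA-256 of each written file, so a run can be reproduced and
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bleach import BleachProtocol, PoolParams, PoolState, Segment, evolve_pools, state_at_end
from .pipeline import (
    DetectionParams,
    Trace,
    compare_pre_post,
    coverslip_summarize,
    detect_evoked,
    detect_spontaneous,
    summarize_synapse,
)
from .synth import NoiseModel, RecordingProtocol, SynapseConfig, generate_trace

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_trace_csv",
    "write_trace_csv",
    "write_events_csv",
    "run_experiment",
]

log = logging.getLogger("iglu")


@dataclass
class ImageStack:
    """A (frames, y, x) stack with its acquisition metadata."""

    data: np.ndarray
    dt: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be (frames, y, x)")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a float32 multi-page TIFF plus its JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"dt": stack.dt, "pixel_size": stack.pixel_size})
    )


def read_stack(path: str | Path, dt: float | None = None, pixel_size: float | None = None) -> ImageStack:
    """Read a multi-page TIFF; metadata from the sidecar unless given."""
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    for key, val in (("dt", dt), ("pixel_size", pixel_size)):
        if val is not None:
            meta[key] = val
        if key not in meta:
            raise KeyError(
                f"missing metadata {key!r}: provide it via the sidecar "
                f"{sc.name} or as an argument"
            )
    return ImageStack(data=data, dt=float(meta["dt"]), pixel_size=float(meta["pixel_size"]))


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> Trace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = float(np.median(np.diff(t)))
    return Trace(df["value"].to_numpy(), dt=dt, t0=float(t[0]))


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Experiment configuration and runner
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "n_synapses": 20,
    "n_coverslips": 2,
    "synapse": {},        # SynapseConfig fields
    "noise": {"sigma": 0.125},
    "detection": {},      # DetectionParams fields
    "recording": {
        "spont_duration": 120.0,
        "n_stims": 20,
        "stim_interval": 5.0,
        "stim_start": 5.0,
        "sample_rate": 50.0,
    },
    "bleach": {"duration": 600.0, "glutamate_perfusion": False},
    "pools": {},          # PoolParams overrides (tau_exchange as mapping)
}


def _validate_config(config: dict) -> dict:
    merged = json.loads(json.dumps(_DEFAULT_CONFIG))
    problems = []
    for key, val in config.items():
        if key not in merged:
            problems.append(f"unknown key {key!r}")
            continue
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                problems.append(f"{key!r} must be a mapping")
            else:
                merged[key].update(val)
        else:
            merged[key] = val
    rec = merged["recording"]
    if rec["stim_interval"] <= 0 or rec["n_stims"] < 0:
        problems.append("recording.stim_interval must be positive, n_stims >= 0")
    if merged["n_synapses"] < 1 or merged["n_coverslips"] < 1:
        problems.append("need at least one synapse and one coverslip")
    if merged["bleach"]["duration"] < 0:
        problems.append("bleach.duration must be non-negative")
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    return merged


def run_experiment(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Simulate, bleach, re-detect and summarize a full pre/post experiment.

    Per synapse: a pre-bleach recording (spontaneous stretch followed by a
    0.2-Hz stimulus train) is simulated and analyzed; the pool model is
    evolved through the bleach protocol; a post-bleach recording is simulated
    with event amplitudes scaled by the resulting unbleached fractions and
    analyzed identically.  Writes per-synapse summaries, post/pre relative
    metrics, per-coverslip means, the model's u-trajectory and a manifest.
    Deterministic for a fixed seed.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfgd = _validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = int(cfgd["seed"])
    scfg = SynapseConfig(**cfgd["synapse"])
    noise = NoiseModel(**cfgd["noise"])
    det = DetectionParams(**cfgd["detection"])
    pool_over = dict(cfgd["pools"])
    if "tau_exchange" in pool_over:
        base = PoolParams().tau_exchange
        base.update(pool_over["tau_exchange"])
        pool_over["tau_exchange"] = base
    pparams = PoolParams(**pool_over)

    rec = cfgd["recording"]
    stims = tuple(
        rec["stim_start"] + i * rec["stim_interval"] for i in range(int(rec["n_stims"]))
    )
    duration = rec["spont_duration"] + (stims[-1] + rec["stim_interval"] if stims else 0.0)
    spont_proto = RecordingProtocol(
        duration=rec["spont_duration"], sample_rate=rec["sample_rate"]
    )
    evoked_proto = RecordingProtocol(
        duration=(stims[-1] + rec["stim_interval"]) if stims else 1.0,
        sample_rate=rec["sample_rate"],
        stim_times=stims,
    )

    bl = cfgd["bleach"]
    if bl["duration"] > 0:
        proto = BleachProtocol(
            (
                Segment(
                    duration=bl["duration"],
                    intensity=1.0,
                    spont_rate=scfg.spont_rate,
                    glutamate_perfusion=bool(bl["glutamate_perfusion"]),
                ),
            )
        )
        traj = evolve_pools(PoolState(), pparams, proto)
        post_state = state_at_end(traj)
    else:
        traj = pd.DataFrame(
            [{"time_s": 0.0, "u_evoked_site": 1.0, "u_synaptic_general": 1.0, "u_reservoir": 1.0}]
        )
        post_state = PoolState()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfgd["n_synapses"])
    rows_pre, rows_rel = [], []
    summaries = []
    for sid in range(cfgd["n_synapses"]):
        rng = np.random.default_rng(children[sid])
        summaries_pp = []
        for pools in (None, post_state):
            tr_sp, _ = generate_trace(scfg, spont_proto, noise, pools=pools, seed=rng, synapse_id=sid)
            tr_ev, _ = generate_trace(scfg, evoked_proto, noise, pools=pools, seed=rng, synapse_id=sid)
            ev_sp = detect_spontaneous(tr_sp, det, synapse_id=sid)
            ev_ev = detect_evoked(tr_ev, stims, det, synapse_id=sid)
            summaries_pp.append(
                summarize_synapse(ev_ev, ev_sp, stims, spont_proto.duration, synapse_id=sid)
            )
        pre, post = summaries_pp
        summaries.append(pre)
        rows_pre.append(
            {"synapse_id": sid, "phase": "pre", "pr": pre.pr, "spont_freq": pre.spont_freq,
             "mean_amp": pre.mean_amp}
        )
        rows_pre.append(
            {"synapse_id": sid, "phase": "post", "pr": post.pr, "spont_freq": post.spont_freq,
             "mean_amp": post.mean_amp}
        )
        rows_rel.append(compare_pre_post(pre, post))

    per_synapse = pd.DataFrame(rows_pre)
    relative = pd.DataFrame(rows_rel)
    grouping = {
        sid: sid % cfgd["n_coverslips"] for sid in range(cfgd["n_synapses"])
    }
    per_coverslip = coverslip_summarize(summaries, grouping)

    written = {}
    for name, df in (
        ("per_synapse.csv", per_synapse),
        ("relative_metrics.csv", relative),
        ("per_coverslip.csv", per_coverslip),
        ("pool_trajectory.csv", traj),
    ):
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        written[name] = _sha256(p)

    manifest = {
        "config": cfgd,
        "seed": seed,
        "version": __version__,
        "outputs": written,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("experiment written to %s", out)
    return out
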