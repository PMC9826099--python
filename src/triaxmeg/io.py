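"""Recording container I/O, run configuration, and the pipeline driver.

Recordings are stored as HDF5 (arrays) plus a JSON sidecar (channel table,
provenance); configs are YAML. Every stochastic stage draws its seed from
the config, and the config hash is embedded in all outputs so any result
file can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .fields import BackgroundField, CoilSystem, InterferenceSource
from .geometry import HeadModel, MotionTrace, RigidTransform, SensorArray, build_helmet_array
from .netstats import aec_connectome, fingerprint_test
from .nulling import run_nulling
from .opm import NoiseModel, calibrate_linewidth
from .recon import bandpass, cubic_grid, estimate_covariance, lcmv, preprocess, pseudo_t_image, virtual_electrode
from .synthpara import (
    Paradigm,
    Recording,
    default_head_model,
    generate_participant,
    generate_recording,
    region_leadfield_matrix,
)

__all__ = ["RunConfig", "write_recording", "read_recording", "run_pipeline"]

SCHEMA_VERSION = 1
logger = logging.getLogger(__name__)

STAGES = ("null", "simulate", "beamform", "connect", "fingerprint")


@dataclass
class RunConfig:
    """Study configuration; defaults mirror the simulated experiment."""

    n_sensors: int = 30
    scalp_radius: float = 0.09
    head_radius: float = 0.08
    n_participants: int = 2
    n_runs: int = 8
    paradigm: dict = dc_field(default_factory=dict)
    background: dict = dc_field(
        default_factory=lambda: {"b0_nT": [1.7, 1.7, 1.7], "g_nT_per_m": [1.7, -1.3, 1.5, 1.2, -1.0]}
    )
    noise_fT_per_rtHz: float = 15.0
    gain_anchor: tuple = (3.0, 0.038)  # (step nT, gain error) linewidth anchor
    interference: dict = dc_field(
        default_factory=lambda: {"frequency": 16.6, "amplitude": 1e-12}
    )
    band: tuple = (13.0, 30.0)
    mu: float = 0.05
    grid_spacing: float = 0.004
    grid_half_extent: float = 0.03
    n_perm: int = 100_000
    seed: int = 0
    nulling_iterations: int = 2
    motion: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        out = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            out[k] = list(v) if isinstance(v, tuple) else v
        return out

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def make_paradigm(self) -> Paradigm:
        return Paradigm(**self.paradigm)

    def make_background(self) -> BackgroundField:
        return BackgroundField.from_config(self.background)

    def make_interference(self) -> InterferenceSource:
        return InterferenceSource(**self.interference)


# ---------------------------------------------------------------------------
# recording round-trip


def write_recording(rec: Recording, path, config_hash: str = "") -> None:
    """Serialize a Recording to HDF5 + a JSON sidecar (same stem, .json)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = rec.fs
        f.attrs["config_hash"] = config_hash
        f.create_dataset("data", data=rec.data)
        trig = f.create_group("triggers")
        trig.create_dataset("samples", data=np.array([s for s, _ in rec.triggers], dtype=np.int64))
        trig.create_dataset(
            "labels", data=np.array([l for _, l in rec.triggers], dtype="S32")
        )
        if rec.motion is not None:
            m = f.create_group("motion")
            m.attrs["fs"] = rec.motion.fs
            m.create_dataset("timestamps", data=rec.motion.timestamps)
            m.create_dataset("rotations", data=np.stack([p.rotation for p in rec.motion.poses]))
            m.create_dataset("translations", data=np.stack([p.translation for p in rec.motion.poses]))
        a = f.create_group("array")
        a.create_dataset("positions", data=rec.array.positions)
        a.create_dataset("axes", data=rec.array.axes)
        a.create_dataset("radial_tags", data=rec.array.radial_tags)
        a.create_dataset("labels", data=np.array(rec.array.labels, dtype="S16"))
        h = f.create_group("head")
        h.create_dataset("center", data=rec.head.center)
        h.attrs["radius"] = rec.head.radius
        f.attrs["provenance"] = json.dumps(rec.provenance, sort_keys=True)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash,
        "provenance": rec.provenance,
        "channels": rec.array.channel_table(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    """Load a Recording written by :func:`write_recording` (lossless)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"schema version mismatch: file has {version}, reader supports {SCHEMA_VERSION}"
            )
        data = f["data"][()]
        samples = f["triggers/samples"][()]
        labels = [s.decode() for s in f["triggers/labels"][()]]
        motion = None
        if "motion" in f:
            poses = tuple(
                RigidTransform(R, t)
                for R, t in zip(f["motion/rotations"][()], f["motion/translations"][()])
            )
            motion = MotionTrace(f["motion/timestamps"][()], poses, fs=float(f["motion"].attrs["fs"]))
        array = SensorArray(
            f["array/positions"][()],
            f["array/axes"][()],
            labels=tuple(s.decode() for s in f["array/labels"][()]),
            radial_tags=f["array/radial_tags"][()],
        )
        head = HeadModel(f["head/center"][()], float(f["head"].attrs["radius"]))
        provenance = json.loads(f.attrs["provenance"])
        fs = float(f.attrs["fs"])
    return Recording(
        data=data,
        fs=fs,
        triggers=tuple(zip(samples.tolist(), labels)),
        motion=motion,
        array=array,
        head=head,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# pipeline driver


class PipelineError(RuntimeError):
    """A stage failed or was requested out of dependency order."""


def run_pipeline(cfg: RunConfig, out_dir=None, stages=STAGES) -> dict:
    """Execute the study pipeline: null -> simulate -> beamform -> connect ->
    fingerprint. Returns (and optionally writes) a JSON-serializable report
    bundle; deterministic for a fixed config.
    """
    stages = tuple(stages)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    order = [s for s in STAGES if s in stages]
    bundle: dict = {"config_hash": cfg.config_hash, "stages": {}}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    master = np.random.default_rng(cfg.seed)
    stage_seeds = {s: int(master.integers(2**31)) for s in STAGES}

    for stage in order:
        t0 = time.time()
        logger.info("stage %s starting (config %s)", stage, cfg.config_hash)
        try:
            if stage == "null":
                report = _stage_null(cfg, stage_seeds["null"])
            elif stage == "simulate":
                report = _stage_simulate(cfg, stage_seeds["simulate"], state, out_dir)
            elif stage == "beamform":
                _require(state, "recordings", stage, "simulate")
                report = _stage_beamform(cfg, state)
            elif stage == "connect":
                _require(state, "recordings", stage, "simulate")
                report = _stage_connect(cfg, state)
            elif stage == "fingerprint":
                _require(state, "connectomes", stage, "connect")
                report = _stage_fingerprint(cfg, state, stage_seeds["fingerprint"])
        except PipelineError:
            raise
        except Exception as exc:  # preserve partial outputs, name the stage
            bundle["stages"][stage] = {"error": str(exc)}
            _write_bundle(bundle, out_dir)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        report["wall_time_s"] = round(time.time() - t0, 3)
        bundle["stages"][stage] = report
    _write_bundle(bundle, out_dir)
    return bundle


def _require(state, key, stage, needs):
    if key not in state:
        raise PipelineError(f"stage {stage!r} requires {needs!r} to run first")


def _write_bundle(bundle, out_dir):
    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(bundle, indent=1, default=float))


def _stage_null(cfg: RunConfig, seed: int) -> dict:
    array = build_helmet_array(cfg.n_sensors, scalp_radius=cfg.scalp_radius)
    coils = CoilSystem.nominal(seed=seed)
    gm = calibrate_linewidth(*cfg.gain_anchor)
    nm = NoiseModel(cfg.noise_fT_per_rtHz, seed=seed)
    rep = run_nulling(
        cfg.make_background(), coils, array, gm, nm,
        iterations=cfg.nulling_iterations, seed=seed,
    )
    return {
        "pre_uniform_norm_nT": rep.pre_uniform_norm,
        "pre_gradient_norm_nT_per_m": rep.pre_gradient_norm,
        "post_uniform_norm_nT": rep.post_uniform_norm,
        "post_gradient_norm_nT_per_m": rep.post_gradient_norm,
        "iterations": list(rep.iterations),
    }


def _stage_simulate(cfg: RunConfig, seed: int, state: dict, out_dir) -> dict:
    rng = np.random.default_rng(seed)
    head = HeadModel(np.zeros(3), cfg.head_radius)
    array = build_helmet_array(cfg.n_sensors, scalp_radius=cfg.scalp_radius)
    paradigm = cfg.make_paradigm()
    gm = calibrate_linewidth(*cfg.gain_anchor)
    participants = [
        generate_participant(f"P{i + 1}", seed=int(rng.integers(2**31)))
        for i in range(cfg.n_participants)
    ]
    recordings = {}
    for p in participants:
        for run in range(cfg.n_runs):
            rec = generate_recording(
                p,
                paradigm=paradigm,
                env=cfg.make_background(),
                interference=cfg.make_interference(),
                gm=gm,
                nm=NoiseModel(cfg.noise_fT_per_rtHz, seed=int(rng.integers(2**31))),
                seed=int(rng.integers(2**31)),
                array=array,
                head=head,
                motion=cfg.motion,
            )
            recordings[(p.id, run)] = rec
            if out_dir is not None:
                write_recording(
                    rec, out_dir / f"{p.id}_run{run}.h5", config_hash=cfg.config_hash
                )
    state["participants"] = participants
    state["recordings"] = recordings
    state["array"], state["head"] = array, head
    return {
        "n_recordings": len(recordings),
        "participants": [p.id for p in participants],
        "runs_per_participant": cfg.n_runs,
    }


def _stage_beamform(cfg: RunConfig, state: dict) -> dict:
    array, head = state["array"], state["head"]
    images = {}
    peaks = {}
    for key, rec in state["recordings"].items():
        epochs = preprocess(rec)
        for cond, ep in epochs.items():
            filt = ep.__class__(
                bandpass(ep.data, *cfg.band, fs=ep.fs), ep.fs, cond,
                ep.channel_indices, ep.labels,
            )
            pid = key[0]
            p = next(pp for pp in state["participants"] if pp.id == pid)
            center = p.centroids[p.motor_regions[0 if cond == "right" else 1]]
            grid = cubic_grid(center, cfg.grid_half_extent, cfg.grid_spacing)
            inside = np.linalg.norm(grid - head.center, axis=1) < 0.95 * head.radius
            img = pseudo_t_image(filt, array, head, grid[inside], mode="triaxial",
                                 mu=cfg.mu, spacing=cfg.grid_spacing)
            images[key + (cond,)] = img
            peaks[str(key + (cond,))] = img.grid[int(np.argmax(np.abs(img.values)))].tolist()
    state["images"] = images
    return {"n_images": len(images), "peaks_m": peaks}


def _stage_connect(cfg: RunConfig, state: dict) -> dict:
    array, head = state["array"], state["head"]
    connectomes = {}
    for key, rec in state["recordings"].items():
        pid = key[0]
        p = next(pp for pp in state["participants"] if pp.id == pid)
        epochs = preprocess(rec)
        for cond, ep in epochs.items():
            filt = bandpass(ep.data, *cfg.band, fs=ep.fs)
            cov = estimate_covariance(filt, mu=cfg.mu)
            cat = filt.transpose(1, 0, 2).reshape(filt.shape[1], -1)
            tcs = np.empty((p.n_regions, cat.shape[1]))
            for r in range(p.n_regions):
                from .fields import leadfield

                L = leadfield(array, p.centroids[r], head)[ep.channel_indices]
                sol = lcmv(cov, L)
                tcs[r] = virtual_electrode(sol, cat)
            connectomes[key + (cond,)] = aec_connectome(tcs, ep.fs, condition=cond)
    state["connectomes"] = connectomes
    return {"n_connectomes": len(connectomes)}


def _stage_fingerprint(cfg: RunConfig, state: dict, seed: int) -> dict:
    out = {}
    conns = state["connectomes"]
    conditions = sorted({k[-1] for k in conns})
    pids = [p.id for p in state["participants"]]
    for cond in conditions:
        vecs = []
        for pid in pids:
            for run in range(cfg.n_runs):
                vecs.append(conns[(pid, run, cond)].upper_triangle())
        if len(vecs) != 16:
            raise PipelineError(
                f"fingerprint stage needs 16 connectomes per condition, got {len(vecs)}"
            )
        res = fingerprint_test(np.stack(vecs), n_perm=cfg.n_perm, seed=seed)
        out[cond] = {
            "observed_between_minus_within": res.observed,
            "p_value": res.p_value,
            "n_within": len(res.within),
            "n_between": len(res.between),
            "n_perm": res.n_perm,
        }
    return out
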