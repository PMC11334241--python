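"""Recording and manifest I/O, run configuration, and the staged pipeline.

On-disk conventions
-------------------
* **Recording**: two-column CSV with header ``time_s,value`` plus a JSON
  sidecar ``<name>.meta.json`` carrying the sampling rate, start time,
  patient id, artifact-mask run-lengths and generator parameters.
* **Segment store**: one ``<patient>.npz`` array container per patient
  (normalized segment matrix, y, t) plus a ``manifest.csv`` with columns
  ``segment_id, patient_id, t, y, source_path, offset, schema_version``
  (t in seconds from recording start, y an artifact fraction in [0, 1]).
* **Pairs**: CSV ``good_segment_id, bad_segment_id, c, patient_id`` plus
  a JSON echo of the pairing configuration.
* **Config**: a single TOML file; unknown keys are rejected, every
  default is explicit in :data:`DEFAULT_CONFIG`.  All outputs embed a
  SHA-256 hash of the resolved configuration, and each stage appends a
  JSON-lines log entry with its seed and that hash.

Times are seconds from recording start; segment windows are half-open
``[t, t + segment_seconds)``.
"""

from __future__ import annotations

import copy
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import quality as q
from .evaluate import at_curve
from .model import ModelConfig, SiamQualityNet, load_checkpoint, save_checkpoint
from .pairing import PairingConfig, QualityPair, find_pairs
from .preprocess import LabeledSegment
from .simulate import ArtifactSchedule, RecordingWithTruth, make_corpus
from .train import FinetuneConfig, PretrainConfig, embed_segments, finetune, pretrain

__all__ = [
    "SCHEMA_VERSION",
    "DEFAULT_CONFIG",
    "write_recording",
    "read_recording",
    "save_segments",
    "load_segments",
    "validate_manifest",
    "ValidationReport",
    "load_config",
    "config_hash",
    "run_pipeline",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    runs = []
    diff = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        runs.append([int(s), int(e - s)])
    return runs


def _runs_to_mask(runs, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, length in runs:
        mask[s:s + length] = True
    return mask


def write_recording(rec: RecordingWithTruth, path) -> Path:
    """Write a recording as ``time_s,value`` CSV with a JSON sidecar."""
    path = Path(path)
    t = rec.start_time + np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_s": t, "value": rec.samples}).to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "start_time": rec.start_time,
        "patient_id": rec.patient_id,
        "n_samples": int(rec.samples.size),
        "mask_runs": _mask_to_runs(rec.artifact_mask),
        "meta": _jsonable(rec.meta),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta))
    return path


def read_recording(path, format: str = "csv") -> RecordingWithTruth:
    """Read a continuous recording.

    Only the CSV format is supported in this build (the ``wfdb`` package
    is not available); the sampling rate comes from the JSON sidecar or,
    failing that, from the (uniform) time column.
    """
    if format == "wfdb":
        raise ValueError(
            "WFDB support requires the 'wfdb' package, which is not "
            "installed; convert the record to time_s,value CSV instead")
    if format != "csv":
        raise ValueError(f"unknown recording format {format!r}")
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError(
            f"{path}: expected header 'time_s,value', got {list(df.columns)}")
    bad = df.index[df[["time_s", "value"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"{path}: malformed value at line {int(bad[0]) + 2}")  # 1-based + header

    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
        mask = _runs_to_mask(meta.get("mask_runs", []), len(df))
        return RecordingWithTruth(
            samples=df["value"].to_numpy(), fs=fs,
            start_time=float(meta.get("start_time", df["time_s"].iloc[0])),
            artifact_mask=mask, patient_id=meta.get("patient_id", path.stem),
            meta=meta.get("meta", {}))
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) == 0:
        raise ValueError(f"{path}: cannot infer sampling rate from one sample")
    if np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12:
        raise ValueError(f"{path}: non-uniform time column and no sidecar fs")
    return RecordingWithTruth(
        samples=df["value"].to_numpy(), fs=float(1.0 / np.median(dt)),
        start_time=float(df["time_s"].iloc[0]), patient_id=path.stem)


# ---------------------------------------------------------------------------
# Segment store and manifest
# ---------------------------------------------------------------------------


def save_segments(segments: list[LabeledSegment], out_dir) -> Path:
    """Write per-patient array containers plus the CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    by_patient: dict[str, list[LabeledSegment]] = {}
    for s in segments:
        by_patient.setdefault(s.patient_id, []).append(s)
    for pid, segs in by_patient.items():
        store = out_dir / f"{pid}.npz"
        np.savez(store,
                 samples=np.stack([s.samples for s in segs]),
                 y=np.array([s.y for s in segs]),
                 t=np.array([s.t for s in segs]),
                 fs=np.array([segs[0].fs]),
                 hr_bpm=np.array([s.meta.get("hr_bpm", np.nan) for s in segs]))
        for off, s in enumerate(segs):
            rows.append({"segment_id": s.segment_id, "patient_id": pid,
                         "t": s.t, "y": s.y, "source_path": store.name,
                         "offset": off, "schema_version": SCHEMA_VERSION})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_segments(seg_dir) -> list[LabeledSegment]:
    """Rebuild labelled segments from a segment store directory."""
    seg_dir = Path(seg_dir)
    manifest = pd.read_csv(seg_dir / "manifest.csv")
    report = validate_manifest(manifest, base_dir=seg_dir)
    if report.errors:
        raise ValueError("invalid manifest: " + "; ".join(report.errors))
    segments = []
    cache: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        src = row["source_path"]
        if src not in cache:
            with np.load(seg_dir / src) as data:
                cache[src] = {k: data[k] for k in data.files}
        store = cache[src]
        off = int(row["offset"])
        meta = {}
        if not np.isnan(store["hr_bpm"][off]):
            meta["hr_bpm"] = float(store["hr_bpm"][off])
        segments.append(LabeledSegment(
            samples=store["samples"][off], y=float(row["y"]),
            t=float(row["t"]), patient_id=row["patient_id"],
            segment_id=row["segment_id"], fs=float(store["fs"][0]), meta=meta))
    return segments


class ValidationReport:
    def __init__(self):
        self.errors: list[str] = []

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_manifest(manifest: pd.DataFrame, base_dir=None) -> ValidationReport:
    """Check manifest integrity: uniqueness, ranges, file references."""
    report = ValidationReport()
    required = {"segment_id", "patient_id", "t", "y", "schema_version"}
    missing = required - set(manifest.columns)
    if missing:
        report.errors.append(f"missing columns: {sorted(missing)}")
        return report
    dup = manifest["segment_id"][manifest["segment_id"].duplicated()]
    for sid in dup.unique():
        report.errors.append(f"duplicate segment_id {sid!r}")
    for idx, y in manifest["y"].items():
        if not 0.0 <= y <= 1.0:
            report.errors.append(f"row {idx}: y={y} outside [0, 1]")
    for idx, t in manifest["t"].items():
        if t < 0:
            report.errors.append(f"row {idx}: negative t={t}")
    if base_dir is not None and "source_path" in manifest.columns:
        for src in manifest["source_path"].unique():
            if not (Path(base_dir) / src).exists():
                report.errors.append(f"missing referenced file {src!r}")
    return report


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_patients": 5, "recording_minutes": 6.0, "fs": 240.0,
        "hr_low": 50.0, "hr_high": 120.0,
        "p_segment": 0.4, "level_lo": 0.3, "level_hi": 0.8,
        "window_fraction": 1.0, "drift_level": 0.1, "powerline_level": 0.0,
    },
    "preprocess": {"segment_seconds": 30.0, "target_fs": 40.0,
                   "labels": "truth"},
    "pair": {"window_seconds": 300.0, "low_quality_threshold": 0.2,
             "anchor_threshold": 0.0, "selection": "max_abs_dt"},
    "model": {"encoder_variant": "tiny_1d", "input_length": 1200,
              "projection_dim": 32, "projector_hidden": 64,
              "predictor_hidden": 16, "stop_gradient": True},
    "pretrain": {"epochs": 3, "batch_size": 8, "learning_rate": 0.02,
                 "curriculum_mode": "staged_buckets", "n_buckets": 5,
                 "loss_scale": 1.0},
    "finetune": {"strategy": "fine_tune_all", "epochs": 40, "batch_size": 16,
                 "learning_rate": 1e-3, "test_fraction": 0.33},
    "evaluate": {"metric": "MAE"},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {here!r} must be a table")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a TOML run configuration merged over explicit defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _merge(DEFAULT_CONFIG, user)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path, cfg_hash: str):
        self.path = path
        self.cfg_hash = cfg_hash
        path.parent.mkdir(parents=True, exist_ok=True)

    def write(self, stage: str, **fields) -> None:
        entry = {"stage": stage, "config_hash": self.cfg_hash,
                 **_jsonable(fields)}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def stage_simulate(config: dict, out_dir: Path, log: _RunLog) -> list[RecordingWithTruth]:
    c = config["simulate"]
    schedule = ArtifactSchedule(
        p_segment=c["p_segment"], level_range=(c["level_lo"], c["level_hi"]),
        window_fraction=c["window_fraction"], drift_level=c["drift_level"],
        powerline_level=c["powerline_level"])
    recs = make_corpus(
        n_patients=int(c["n_patients"]), recording_minutes=c["recording_minutes"],
        fs=c["fs"], hr_range=(c["hr_low"], c["hr_high"]),
        artifact_schedule=schedule, seed=int(config["seed"]))
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        write_recording(rec, rec_dir / f"{rec.patient_id}.csv")
    log.write("simulate", seed=config["seed"], n_recordings=len(recs))
    return recs


def stage_preprocess(config: dict, out_dir: Path, log: _RunLog,
                     recordings: list[RecordingWithTruth] | None = None) -> list[LabeledSegment]:
    c = config["preprocess"]
    if recordings is None:
        rec_dir = out_dir / "recordings"
        if not rec_dir.exists():
            raise FileNotFoundError(f"expected recordings at {rec_dir}")
        recordings = [read_recording(p) for p in sorted(rec_dir.glob("*.csv"))]
    segments: list[LabeledSegment] = []
    for rec in recordings:
        raw = pp.segment_recording(rec, c["segment_seconds"])
        if c["labels"] == "estimate":
            labels = {seg.index: q.assess(seg.samples, seg.fs).y_estimate
                      for seg in raw}
            segments.extend(pp.label_segments(raw, rec=rec, labels=labels,
                                              target_fs=c["target_fs"]))
        else:
            segments.extend(pp.label_segments(raw, rec=rec,
                                              target_fs=c["target_fs"]))
    save_segments(segments, out_dir / "segments")
    log.write("preprocess", n_segments=len(segments))
    return segments


def stage_pair(config: dict, out_dir: Path, log: _RunLog,
               segments: list[LabeledSegment] | None = None) -> list[QualityPair]:
    if segments is None:
        segments = load_segments(out_dir / "segments")
    c = config["pair"]
    pc = PairingConfig(window_seconds=c["window_seconds"],
                       low_quality_threshold=c["low_quality_threshold"],
                       anchor_threshold=c["anchor_threshold"],
                       selection=c["selection"])
    pairs = find_pairs(segments, pc)
    df = pd.DataFrame([{"good_segment_id": p.good.segment_id,
                        "bad_segment_id": p.bad.segment_id,
                        "c": p.c, "patient_id": p.good.patient_id}
                       for p in pairs])
    df.to_csv(out_dir / "pairs.csv", index=False)
    (out_dir / "pairing_config.json").write_text(json.dumps(_jsonable(c)))
    log.write("pair", n_pairs=len(pairs))
    return pairs


def _model_config(config: dict) -> ModelConfig:
    m = config["model"]
    return ModelConfig(encoder_variant=m["encoder_variant"],
                       input_length=int(m["input_length"]),
                       projection_dim=int(m["projection_dim"]),
                       projector_hidden=int(m["projector_hidden"]),
                       predictor_hidden=int(m["predictor_hidden"]),
                       stop_gradient=bool(m["stop_gradient"]))


def stage_pretrain(config: dict, out_dir: Path, log: _RunLog,
                   pairs: list[QualityPair] | None = None) -> SiamQualityNet:
    if pairs is None:
        segments = load_segments(out_dir / "segments")
        pairs = stage_pair(config, out_dir, log, segments)
    c = config["pretrain"]
    pc = PretrainConfig(epochs=int(c["epochs"]), batch_size=int(c["batch_size"]),
                        learning_rate=c["learning_rate"],
                        curriculum_mode=c["curriculum_mode"],
                        n_buckets=int(c["n_buckets"]),
                        loss_scale=c["loss_scale"], seed=int(config["seed"]))
    model, trace = pretrain(pairs, model_config=_model_config(config), config=pc)
    save_checkpoint(model, out_dir / "checkpoint.npz")
    with open(out_dir / "pretrain_log.jsonl", "w") as fh:
        for i, (loss, c_mean) in enumerate(zip(trace.step_losses,
                                               trace.batch_mean_c)):
            fh.write(json.dumps({"step": i, "loss": loss,
                                 "batch_mean_c": c_mean}) + "\n")
        for e, (ml, disp) in enumerate(zip(trace.epoch_mean_loss,
                                           trace.epoch_dispersion)):
            fh.write(json.dumps({"epoch": e, "mean_loss": ml,
                                 "dispersion": disp}) + "\n")
    log.write("pretrain", seed=config["seed"],
              final_loss=trace.epoch_mean_loss[-1],
              dispersion=trace.epoch_dispersion[-1])
    return model


def stage_finetune(config: dict, out_dir: Path, log: _RunLog,
                   model: SiamQualityNet | None = None,
                   segments: list[LabeledSegment] | None = None) -> pd.DataFrame:
    """Fine-tune on the synthetic heart-rate regression task.

    Targets are the generator heart rates carried in segment metadata.
    Writes per-test-segment predictions for the evaluation stage.
    """
    if model is None:
        ckpt = out_dir / "checkpoint.npz"
        if not ckpt.exists():
            raise FileNotFoundError(f"expected checkpoint at {ckpt}")
        model = load_checkpoint(ckpt)
    if segments is None:
        segments = load_segments(out_dir / "segments")
    c = config["finetune"]
    usable = [s for s in segments if "hr_bpm" in s.meta]
    if not usable:
        raise ValueError("no segments carry an hr_bpm target")
    X = np.stack([s.samples for s in usable])
    y = np.array([s.meta["hr_bpm"] for s in usable])
    quality = np.array([s.y for s in usable])
    rng = np.random.default_rng(int(config["seed"]) + 1)
    order = rng.permutation(len(usable))
    n_test = max(1, int(round(c["test_fraction"] * len(usable))))
    test_idx, train_idx = order[:n_test], order[n_test:]
    fc = FinetuneConfig(strategy=c["strategy"], task_kind="regression",
                        epochs=int(c["epochs"]), batch_size=int(c["batch_size"]),
                        learning_rate=c["learning_rate"], seed=int(config["seed"]))
    task, test_mae = finetune(model, X[train_idx], y[train_idx], fc,
                              X_val=X[test_idx], y_val=y[test_idx])
    pred = task.predict(X[test_idx])
    df = pd.DataFrame({
        "segment_id": [usable[i].segment_id for i in test_idx],
        "quality_y": quality[test_idx],
        "target": y[test_idx],
        "prediction": pred,
    })
    df.to_csv(out_dir / "predictions.csv", index=False)
    log.write("finetune", seed=config["seed"], strategy=c["strategy"],
              test_mae=test_mae, n_train=len(train_idx), n_test=len(test_idx))
    return df


def stage_evaluate(config: dict, out_dir: Path, log: _RunLog,
                   predictions: pd.DataFrame | None = None) -> pd.DataFrame:
    if predictions is None:
        path = out_dir / "predictions.csv"
        if not path.exists():
            raise FileNotFoundError(f"expected predictions at {path}")
        predictions = pd.read_csv(path)
    metric = config["evaluate"]["metric"]
    curve = at_curve(predictions["quality_y"], predictions["target"],
                     predictions["prediction"], metric_name=metric)
    df = pd.DataFrame(curve.to_records())
    df.to_csv(out_dir / "atcurve.csv", index=False)
    log.write("evaluate", metric=metric,
              overall=curve.subgroup_metric[-1])
    return df


def run_pipeline(config: dict | None = None, out_dir=".") -> dict:
    """Run simulate -> preprocess -> pair -> pretrain -> finetune -> evaluate.

    Every stage writes its artifacts under ``out_dir`` and appends to the
    JSON-lines run log; each stage is also runnable standalone from the
    prior stage's on-disk artifacts.  Returns paths of the key outputs.
    """
    config = config or load_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run_log.jsonl", config_hash(config))
    recs = stage_simulate(config, out_dir, log)
    segments = stage_preprocess(config, out_dir, log, recordings=recs)
    pairs = stage_pair(config, out_dir, log, segments)
    model = stage_pretrain(config, out_dir, log, pairs)
    preds = stage_finetune(config, out_dir, log, model, segments)
    stage_evaluate(config, out_dir, log, preds)
    return {
        "out_dir": str(out_dir),
        "manifest": str(out_dir / "segments" / "manifest.csv"),
        "pairs": str(out_dir / "pairs.csv"),
        "checkpoint": str(out_dir / "checkpoint.npz"),
        "predictions": str(out_dir / "predictions.csv"),
        "atcurve": str(out_dir / "atcurve.csv"),
        "log": str(out_dir / "run_log.jsonl"),
        "config_hash": config_hash(config),
    }


def write_embeddings(model: SiamQualityNet, segments: list[LabeledSegment],
                     path, space: str = "h") -> Path:
    """Export embeddings with annotations for external 2-D reduction."""
    X = np.stack([s.samples for s in segments])
    emb = embed_segments(model, X, space=space)
    df = pd.DataFrame(emb, columns=[f"e{i}" for i in range(emb.shape[1])])
    df.insert(0, "segment_id", [s.segment_id for s in segments])
    df.insert(1, "patient_id", [s.patient_id for s in segments])
    df.insert(2, "y", [s.y for s in segments])
    df.insert(3, "hr_bpm", [s.meta.get("hr_bpm", np.nan) for s in segments])
    df.to_csv(path, index=False)
    return Path(path)
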