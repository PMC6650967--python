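"""Stream/model/report serialization and the end-to-end pipeline.

Streams are plain CSV (seconds-based timestamps, one row per sample):

* IMU: header ``t,ay,gy`` (SI units: m/s^2, deg/s)
* FSR: header ``t,heel,mt1,mt5,toe``
* labels: header ``t,phase`` with phases as HS/FF/HO/SP strings

Configurations, models and evaluation reports are JSON.  ``run_pipeline``
chains simulate/load -> preprocess -> reference labeling -> detector ->
evaluation, stamping every artifact with the config hash and seed so two
runs with equal configuration are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from .fsr import PatternConfig, binarize_fsr, label_from_fsr
from .hmm import features_from_gyro
from .models import GaitPhaseHMM, ThresholdDetector
from .phases import GaitPhase, LabelSequence
from .preprocessing import preprocess_imu
from .simulate import (GaitSimParams, generator_matched_tb_config,
                       healthy_preset, pathological_preset, simulate_trial)
from .streams import FsrStream, ImuStream


class StreamParseError(ValueError):
    pass


_HEADERS = {"imu": ["t", "ay", "gy"],
            "fsr": ["t", "heel", "mt1", "mt5", "toe"],
            "labels": ["t", "phase"]}


def _infer_fs(t: np.ndarray, path: str) -> float:
    dt = np.diff(t)
    if t.size < 2:
        raise StreamParseError(f"{path}: need at least 2 samples to infer the rate")
    if np.any(dt <= 0) or np.max(np.abs(dt - dt.mean())) > 1e-6:
        bad = int(np.argmax(np.abs(dt - dt.mean()))) + 2
        raise StreamParseError(f"{path}: non-uniform timestamps near line {bad}")
    return 1.0 / dt.mean()


def read_stream(path, kind: str):
    """Read a CSV stream; the rate is inferred from the timestamps."""
    if kind not in _HEADERS:
        raise ValueError("kind must be 'imu', 'fsr' or 'labels'")
    df = pd.read_csv(path)
    missing = [c for c in _HEADERS[kind] if c not in df.columns]
    if missing:
        raise StreamParseError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    fs = _infer_fs(t, str(path))
    fs = round(fs, 6)
    if kind == "imu":
        return ImuStream(t, df["ay"].to_numpy(float), df["gy"].to_numpy(float), fs)
    if kind == "fsr":
        return FsrStream(t, df["heel"].to_numpy(float), df["mt1"].to_numpy(float),
                         df["mt5"].to_numpy(float), df["toe"].to_numpy(float), fs)
    return LabelSequence.from_names(df["phase"].tolist(), fs, t0=float(t[0]))


def write_stream(path, obj) -> None:
    """Write an ImuStream / FsrStream / LabelSequence as CSV."""
    if isinstance(obj, ImuStream):
        df = pd.DataFrame({"t": obj.t, "ay": obj.ay, "gy": obj.gy})
    elif isinstance(obj, FsrStream):
        df = pd.DataFrame({"t": obj.t, "heel": obj.heel, "mt1": obj.mt1,
                           "mt5": obj.mt5, "toe": obj.toe})
    elif isinstance(obj, LabelSequence):
        df = pd.DataFrame({"t": obj.t, "phase": obj.phase_names()})
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    df.to_csv(path, index=False, float_format="%.6f")


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    detector: str = "hmm-sst"       # 'tb' | 'hmm-sst'
    preset: str = "healthy"         # 'healthy' | 'pathological'
    severity: float = 0.5           # pathological preset only
    n_strides: int = 12
    seed: int = 0
    tolerance_ms: float = ev.TOLERANCE_MS
    median_window: int = 5
    accel_cutoff: float = 17.0
    gyro_cutoff: float = 15.0
    imu_path: str | None = None     # load instead of simulate when set
    fsr_path: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Simulate/load, label, detect and evaluate; return the report dict."""
    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(name, exc) from exc

    if cfg.imu_path and cfg.fsr_path:
        imu = stage("load", lambda: read_stream(cfg.imu_path, "imu"))
        fsr = stage("load", lambda: read_stream(cfg.fsr_path, "fsr"))
        trials = None
    else:
        if cfg.preset == "pathological":
            params = pathological_preset(cfg.severity, n_strides=cfg.n_strides,
                                         seed=cfg.seed)
        else:
            params = healthy_preset(n_strides=cfg.n_strides, seed=cfg.seed)
        trials = stage("simulate", lambda: [
            simulate_trial(dataclasses.replace(params, seed=cfg.seed + k))
            for k in range(3)])
        imu, fsr = trials[-1].imu, trials[-1].fsr

    pp = lambda s: preprocess_imu(s, median_window=cfg.median_window,
                                  accel_cutoff=cfg.accel_cutoff,
                                  gyro_cutoff=cfg.gyro_cutoff, fs_out=200.0)
    ref = stage("reference", lambda: label_from_fsr(binarize_fsr(fsr)))

    if cfg.detector == "tb":
        det = ThresholdDetector(generator_matched_tb_config())
        pred = stage("detect", lambda: det.detect(pp(imu)))
    elif cfg.detector == "hmm-sst":
        if trials is None:
            raise PipelineError("train", ValueError(
                "hmm-sst needs three simulated trials; supply detector='tb' "
                "for single-trial file input"))
        pairs = [(features_from_gyro(pp(tr.imu).gy, 200.0),
                  label_from_fsr(binarize_fsr(tr.fsr))) for tr in trials]
        model = stage("train", lambda: GaitPhaseHMM(
            [p[0] for p in pairs[:2]], [p[1] for p in pairs[:2]]).fit(seed=cfg.seed))
        pred = stage("detect", lambda: model.predict(pairs[2][0]))
        ref = pairs[2][1]
    else:
        raise PipelineError("config", ValueError(f"unknown detector {cfg.detector!r}"))

    n = min(len(pred), len(ref))
    pred = LabelSequence(pred.labels[:n], pred.fs, t0=pred.t0)
    ref = LabelSequence(ref.labels[:n], ref.fs, t0=ref.t0)
    score = stage("evaluate", lambda: ev.sample_metrics(pred, ref, cfg.tolerance_ms))
    terr = stage("evaluate", lambda: ev.timing_errors(pred, ref))

    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "detector": cfg.detector,
        "n_samples": n,
        "tpr": score.tpr, "tnr": score.tnr, "g": score.g,
        "macro_g": score.macro_g,
        "accuracy_pct": score.accuracy_pct,
        "confusion_pct": np.round(score.confusion_pct, 6).tolist(),
        "timing_mean_ms": {p: (None if np.isnan(terr.mean_ms(p)) else
                               round(terr.mean_ms(p), 3))
                           for p in ("HS", "FF", "HO", "SP")},
        "timing_missed": terr.misses,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_stream(out_dir / "pred_labels.csv", pred)
        write_stream(out_dir / "ref_labels.csv", ref)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
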