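"""Stream readers/writers, run configuration and the end-to-end pipeline.

CSV dialect: comma-separated, header ``t,hf,cf,ax,ay,az``; NDJSON: one
object per sample with the same keys.  Time is seconds from stream
start.  Ground truth (when present) lives in a sibling file with suffix
``.truth`` holding the simulator's reference trajectories.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .artifact import ArtifactParams
from .calibration import ArtifactCalibrator
from .metabolic import MetabolicCNNRegressor, predict_metabolic, spectrogram_dataset
from .simulate import (
    CF_GAIN_V_PER_C,
    CF_OFFSET_V,
    ExerciseProtocol,
    NoiseConfig,
    PhysioGroundTruth,
    SensorStream,
    calibration_protocol,
    synth_session,
)
from .vitals import TempCalibration, sliding_vitals

__all__ = [
    "read_stream",
    "write_stream",
    "read_protocol",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("pulseband")

STREAM_COLUMNS = ["t", "hf", "cf", "ax", "ay", "az"]
TRUTH_COLUMNS = [
    "heart_rate",
    "metabolic_rate",
    "core_temp",
    "clean_pulse",
    "artifact",
    "baseline",
]


def _truth_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth")


def write_stream(
    stream: SensorStream, path, fmt: Literal["csv", "ndjson"] = "csv"
) -> None:
    """Write a stream (and its ground truth, when present) to disk."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": stream.t,
            "hf": stream.hf,
            "cf": stream.cf,
            "ax": stream.acc[:, 0],
            "ay": stream.acc[:, 1],
            "az": stream.acc[:, 2],
        }
    )
    if fmt == "csv":
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "ndjson":
        with open(path, "w") as fh:
            for rec in df.itertuples(index=False):
                fh.write(json.dumps(dict(zip(STREAM_COLUMNS, rec))) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if stream.truth is not None:
        tr = stream.truth
        tdf = pd.DataFrame(
            {
                "heart_rate": tr.heart_rate,
                "metabolic_rate": tr.metabolic_rate,
                "core_temp": tr.core_temp,
                "clean_pulse": tr.clean_pulse,
                "artifact": tr.artifact,
                "baseline": tr.baseline,
            }
        )
        tdf.to_csv(_truth_path(path), index=False, float_format="%.17g")


def read_stream(
    path, fmt: Optional[Literal["csv", "ndjson"]] = None, fs: float = 100.0
) -> SensorStream:
    """Read a stream, validating the uniform time grid at the declared rate.

    A gap or duplicate timestamp raises with the first offending sample
    index; a wrong column set raises listing the missing columns.  When
    a ``.truth`` sibling exists the ground truth is attached.
    """
    path = Path(path)
    if fmt is None:
        fmt = "ndjson" if path.suffix in {".ndjson", ".jsonl"} else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    else:
        df = pd.DataFrame([json.loads(line) for line in path.read_text().splitlines()])
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stream file {path} is missing columns: {missing}")
    t = df["t"].to_numpy(float)
    dt = np.diff(t)
    bad = np.flatnonzero(np.abs(dt - 1.0 / fs) > 1e-6 / fs)
    if bad.size:
        raise ValueError(
            f"non-uniform time grid at sample index {int(bad[0]) + 1}: "
            f"dt={dt[bad[0]]:.6g}s, expected {1.0 / fs:.6g}s"
        )
    truth = None
    tp = _truth_path(path)
    if tp.exists():
        tdf = pd.read_csv(tp, float_precision="round_trip")
        truth = PhysioGroundTruth(
            heart_rate=tdf["heart_rate"].to_numpy(float),
            metabolic_rate=tdf["metabolic_rate"].to_numpy(float),
            core_temp=tdf["core_temp"].to_numpy(float),
            clean_pulse=tdf["clean_pulse"].to_numpy(float),
            artifact=tdf["artifact"].to_numpy(float),
            baseline=tdf["baseline"].to_numpy(float),
        )
    return SensorStream(
        t=t,
        hf=df["hf"].to_numpy(float),
        cf=df["cf"].to_numpy(float),
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        fs=fs,
        truth=truth,
    )


def read_protocol(path, fs: float = 100.0) -> ExerciseProtocol:
    """Load an exercise protocol from a YAML file.

    Expected layout::

        sampling_rate: 100
        segments:
          - [rest, 300, 0.0]
          - [run_9kmh, 300, 0.85]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    segments = [(str(s[0]), float(s[1]), float(s[2])) for s in raw["segments"]]
    return ExerciseProtocol(
        segments=segments, sampling_rate=float(raw.get("sampling_rate", fs))
    )


class RunConfig(BaseModel):
    """Validated configuration of the end-to-end demo pipeline."""

    model_config = ConfigDict(extra="forbid")

    sampling_rate: float = 100.0
    band: tuple[float, float] = (0.5, 5.0)
    beat_length: int = 100
    seed: int = 0
    # simulation
    segment_s: float = 60.0
    true_K: float = 0.12
    true_zeta: float = 0.4
    true_omega_hz: float = 6.0
    # Bayesian optimization
    bo_inits: int = 8
    bo_max_iters: int = 40
    bo_ei_tol: float = 1e-8
    # metabolic training
    train_lr: float = 2e-3
    train_epochs: int = 15
    train_hop_s: float = 3.0
    # outputs
    out_dir: str = "pulseband_run"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_temp_calibration() -> TempCalibration:
    """Inverse of the simulator's cold-film sensor model."""
    return TempCalibration(gain=1.0 / CF_GAIN_V_PER_C, offset=-CF_OFFSET_V / CF_GAIN_V_PER_C)


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate, calibrate, extract vitals and predict metabolic rate.

    Writes params.json, vitals.csv, met.csv and report.json into
    ``cfg.out_dir``; every file's report entry carries the config hash
    and seed.  Any stage failure aborts with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}}
    from .simulate import default_protocol  # local import avoids cycle noise

    stage = "simulate"
    try:
        log.info("stage=%s seed=%d hash=%s", stage, cfg.seed, chash)
        true_params = ArtifactParams(
            K=cfg.true_K, zeta=cfg.true_zeta,
            omega_n=2 * np.pi * cfg.true_omega_hz, fs=cfg.sampling_rate,
        )
        cal_stream = synth_session(
            calibration_protocol(fs=cfg.sampling_rate), true_params,
            NoiseConfig(), seed=cfg.seed,
        )
        session = synth_session(
            default_protocol(segment_s=cfg.segment_s, fs=cfg.sampling_rate),
            true_params, NoiseConfig(), seed=cfg.seed + 1,
        )
        write_stream(cal_stream, out / "calibration.csv")
        write_stream(session, out / "session.csv")
        report["stages"][stage] = {
            "calibration_samples": len(cal_stream.t),
            "session_samples": len(session.t),
        }

        stage = "calibrate"
        log.info("stage=%s", stage)
        cal = ArtifactCalibrator(
            band=cfg.band, beat_length=cfg.beat_length,
            n_init=cfg.bo_inits, max_iters=cfg.bo_max_iters,
            ei_tol=cfg.bo_ei_tol, seed=cfg.seed,
        ).fit(cal_stream)
        (out / "params.json").write_text(cal.params_.to_json())
        report["stages"][stage] = {
            "params": json.loads(cal.params_.to_json()),
            "n_evaluations": cal.report_["n_evaluations"],
        }

        stage = "vitals"
        log.info("stage=%s", stage)
        vdf = sliding_vitals(session, cal.params_, default_temp_calibration(),
                             band=cfg.band, beat_length=cfg.beat_length)
        vdf.to_csv(out / "vitals.csv", index=False)
        report["stages"][stage] = {"records": len(vdf)}

        stage = "metabolic"
        log.info("stage=%s", stage)
        X, y, _ = spectrogram_dataset(session, hop_s=cfg.train_hop_s)
        model = MetabolicCNNRegressor(
            lr=cfg.train_lr, epochs=cfg.train_epochs, seed=cfg.seed
        ).fit(X, y)
        mdf = predict_metabolic(model, session, hop_s=cfg.train_hop_s)
        mdf.to_csv(out / "met.csv", index=False)
        report["stages"][stage] = {
            "train_windows": len(y),
            "final_loss": model.loss_curve_[-1],
            "predictions": len(mdf),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
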