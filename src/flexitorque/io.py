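"""CSV/JSON readers and writers for trials, profiles, models and reports."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import TorqueModel
from .preprocess import ConnaturalProfile, StrainSeries
from .synthetic import ProtocolConfig, TrialRecording

TRIAL_COLUMNS = ["time_s", "angle_deg", "torque_Nm", "circumference_mm"]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return getattr(obj, "__name__", repr(obj))
    return obj


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def write_trial(path, trial: TrialRecording) -> None:
    df = pd.DataFrame({
        "time_s": trial.time,
        "angle_deg": trial.angle,
        "torque_Nm": trial.torque,
        "circumference_mm": trial.circumference,
    })
    df.to_csv(path, index=False)


def read_trial(path, mode: str = "isokinetic", rom=None, velocity=None,
               impedance=None, n_cycles: int = 4, seed: int = 0,
               subject_id: str = "") -> TrialRecording:
    """Load a trial CSV; protocol metadata not stored in the CSV is supplied
    via arguments or inferred from the signals (ROM, sample rate, velocity)."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"trial CSV {path} lacks columns {missing}")
    t = df["time_s"].to_numpy(float)
    angle = df["angle_deg"].to_numpy(float)
    if rom is None:
        rom = (float(5 * round(angle.min() / 5)), float(5 * round(angle.max() / 5)))
    fs = float(1.0 / np.median(np.diff(t))) if t.size > 1 else 100.0
    if velocity is None and mode in ("isokinetic", "passive"):
        rate = np.abs(np.diff(angle)) * fs
        velocity = float(np.median(rate[rate > 1e-6])) if np.any(rate > 1e-6) else 90.0
    protocol = ProtocolConfig(mode=mode, rom=tuple(rom), velocity=velocity,
                              impedance=impedance, n_cycles=n_cycles,
                              sample_rate=fs, seed=seed)
    return TrialRecording(t, angle, df["torque_Nm"].to_numpy(float),
                          df["circumference_mm"].to_numpy(float),
                          protocol, subject_id=subject_id)


def write_profile(path, profile: ConnaturalProfile) -> None:
    lo, hi = profile.rom
    with open(path, "w") as fh:
        fh.write(f"# rom_deg {lo} {hi}\n")
        fh.write("angle_deg,c0_mm\n")
        for a, c in zip(profile.angle, profile.c0):
            fh.write(f"{float(a)!r},{float(c)!r}\n")


def read_profile(path) -> ConnaturalProfile:
    text = Path(path).read_text().splitlines()
    rom = None
    if text and text[0].startswith("#"):
        parts = text[0].split()
        rom = (float(parts[-2]), float(parts[-1]))
    df = pd.read_csv(path, comment="#")
    angle = df["angle_deg"].to_numpy(float)
    if rom is None:
        rom = (float(angle.min()), float(angle.max()))
    return ConnaturalProfile(angle, df["c0_mm"].to_numpy(float), rom=rom)


def write_strain(path, series: StrainSeries) -> None:
    df = pd.DataFrame({
        "angle_deg": series.angle,
        "circumference_rect_mm": series.circumference_rect,
        "strain": series.strain,
        "valid": series.valid.astype(int),
    })
    if series.torque is not None:
        df["torque_Nm"] = series.torque
    if series.time is not None:
        df.insert(0, "time_s", series.time)
    df.to_csv(path, index=False)


def read_strain(path) -> StrainSeries:
    df = pd.read_csv(path)
    series = StrainSeries(
        df["angle_deg"].to_numpy(float),
        df["strain"].to_numpy(float),
        df["circumference_rect_mm"].to_numpy(float),
        df["valid"].to_numpy(bool),
    )
    if "torque_Nm" in df.columns:
        series.torque = df["torque_Nm"].to_numpy(float)
    if "time_s" in df.columns:
        series.time = df["time_s"].to_numpy(float)
    return series


def write_model(model_dir, model: TorqueModel) -> None:
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "angle_deg": model.angle,
        "eta_bar_Nm": model.eta_bar,
        "valid": model.valid.astype(int),
    }).to_csv(model_dir / "eta_bar.csv", index=False)
    write_json(model_dir / "meta.json", model.meta)


def read_model(model_dir) -> TorqueModel:
    model_dir = Path(model_dir)
    df = pd.read_csv(model_dir / "eta_bar.csv")
    meta_path = model_dir / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TorqueModel(df["angle_deg"].to_numpy(float),
                       df["eta_bar_Nm"].to_numpy(float),
                       df["valid"].to_numpy(bool), meta)


def write_prediction(path, series: StrainSeries, predicted) -> None:
    df = pd.DataFrame({
        "angle_deg": series.angle,
        "strain": series.strain,
        "torque_meas_Nm": series.torque if series.torque is not None
        else np.full(series.angle.size, np.nan),
        "torque_pred_Nm": np.asarray(predicted, dtype=float),
    })
    if series.time is not None:
        df.insert(0, "time_s", series.time)
    df.to_csv(path, index=False)
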