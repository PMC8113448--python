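"""File formats: acceleration CSV + JSON sidecar, truth/feature/label/parameter
tables, and classifier model artifacts.

All tabular formats are plain CSV so every output round-trips through its
reader without loss of information relevant downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd

from .classifier import SleepWakeClassifier
from .types import (
    LYING,
    UPRIGHT,
    AccelRecord,
    InputError,
    SensorConfig,
    SleepParameters,
    SleepWakeSeries,
    SubjectMeta,
    labels_from_str,
    labels_to_str,
)

__all__ = [
    "write_acceleration",
    "read_acceleration",
    "write_truth",
    "read_truth",
    "write_features",
    "read_features",
    "write_labels",
    "read_labels",
    "params_to_row",
    "write_params_table",
    "read_params_table",
    "save_model",
    "load_model",
]

_POSTURE_STR = {UPRIGHT: "upright", LYING: "lying"}
_POSTURE_CODE = {v: k for k, v in _POSTURE_STR.items()}


def _meta_to_dict(meta: SubjectMeta) -> dict:
    d = asdict(meta)
    d["recording_start"] = meta.recording_start.isoformat()
    return d


def _meta_from_dict(d: dict) -> SubjectMeta:
    d = dict(d)
    d["recording_start"] = datetime.fromisoformat(d["recording_start"])
    return SubjectMeta(**d)


def write_acceleration(record: AccelRecord, out_dir: Path, subject_id: Optional[str] = None) -> Path:
    """Write ``<id>.csv`` (t_s,ax_g,ay_g,az_g) plus ``<id>.meta.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject_id or record.meta.subject_id
    path = out_dir / f"{sid}.csv"
    t = np.arange(record.n_samples) / record.sensor.sampling_rate
    df = pd.DataFrame(
        {"t_s": t, "ax_g": record.samples[:, 0], "ay_g": record.samples[:, 1],
         "az_g": record.samples[:, 2]}
    )
    # the 10-bit grid (multiples of range/2^(bits-1)) terminates within
    # 9 decimal places, so this representation is lossless
    df.to_csv(path, index=False, float_format="%.9f")
    sidecar = {"meta": _meta_to_dict(record.meta), "sensor": asdict(record.sensor)}
    (out_dir / f"{sid}.meta.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_acceleration(path: Path) -> AccelRecord:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("ax_g", "ay_g", "az_g"):
        if col not in df.columns:
            raise InputError(f"{path} lacks column '{col}'")
    sidecar_path = path.with_suffix("").with_suffix(".meta.json") \
        if path.name.endswith(".meta.json") else path.parent / f"{path.stem}.meta.json"
    if not sidecar_path.exists():
        raise InputError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    return AccelRecord(
        samples=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        sensor=SensorConfig(**sidecar["sensor"]),
        meta=_meta_from_dict(sidecar["meta"]),
    )


def write_truth(posture: np.ndarray, state: np.ndarray, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "minute": np.arange(len(posture)),
            "posture": [_POSTURE_STR[int(p)] for p in posture],
            "state": labels_to_str(state),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_truth(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    posture = np.array([_POSTURE_CODE[p] for p in df["posture"]], dtype=int)
    state = labels_from_str(df["state"].tolist())
    return posture, state


_FEATURE_FILE_COLUMNS = [
    "minute", "tilt_vertical_deg", "tilt_ml_deg", "tilt_ap_deg", "tpower", "valid",
]


def write_features(features: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features[_FEATURE_FILE_COLUMNS].to_csv(path, index=False)
    return path


def read_features(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_FEATURE_FILE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path} lacks columns: {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_labels(series: SleepWakeSeries, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "minute": np.arange(series.minute_offset, series.minute_offset + len(series)),
            "label": labels_to_str(series.labels),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_labels(path: Path) -> SleepWakeSeries:
    df = pd.read_csv(path)
    labels = labels_from_str(df["label"].tolist())
    offset = int(df["minute"].iloc[0]) if len(df) else 0
    return SleepWakeSeries(labels=labels, minute_offset=offset, source="predicted")


PARAMS_COLUMNS = [
    "subject_id", "age", "gender", "month", "ibt_hhmm", "gut_hhmm",
    "tib_min", "sl_min", "waso_min", "tst_min", "se_pct", "qc_flags",
]


def params_to_row(meta: SubjectMeta, params: SleepParameters, qc_flags: str = "") -> dict:
    return {
        "subject_id": meta.subject_id,
        "age": meta.age,
        "gender": meta.gender,
        "month": meta.recording_month,
        "ibt_hhmm": params.ibt_hhmm,
        "gut_hhmm": params.gut_hhmm,
        "tib_min": params.tib,
        "sl_min": params.sl,
        "waso_min": params.waso,
        "tst_min": params.tst,
        "se_pct": round(params.se, 4),
        "qc_flags": qc_flags,
    }


def _hhmm_to_minutes(hhmm: str) -> float:
    h, m = hhmm.split(":")
    return 60 * int(h) + int(m)


def write_params_table(rows: list[dict], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=PARAMS_COLUMNS).to_csv(path, index=False)
    return path


def read_params_table(path: Path) -> pd.DataFrame:
    """Read a parameters CSV and add modelling columns (minutes from midnight)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = set(PARAMS_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path} lacks columns: {sorted(missing)}")
    df["ibt_mfm"] = [_hhmm_to_minutes(x) for x in df["ibt_hhmm"]]
    df["gut_mfm"] = [_hhmm_to_minutes(x) for x in df["gut_hhmm"]]
    return df


def save_model(model: SleepWakeClassifier, path: Path) -> Path:
    """Persist a trained classifier: joblib weights + JSON header sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    header = {
        "format": "trunksleep-svm/1",
        "best_params": getattr(model, "best_params_", None),
        "feature_means": getattr(model, "feature_means_", np.zeros(0)).tolist(),
        "feature_scales": getattr(model, "feature_scales_", np.zeros(0)).tolist(),
        "n_train_minutes": getattr(model, "n_train_minutes_", None),
        "random_state": model.random_state,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))
    return path


def load_model(path: Path) -> SleepWakeClassifier:
    return joblib.load(path)
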