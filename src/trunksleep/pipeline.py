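"""End-to-end orchestration: simulate -> features -> classify -> score -> analyze.

``run_pipeline`` mirrors the flow of a cohort study: raw records pass an
inclusion screen, the classifier converts included records into minute
labels, the in-bed period is detected from posture/activity features, the
seven sleep parameters are scored, and the cohort GLM analysis runs on the
resulting table.  A manifest records per-stage counts (generated, included,
excluded by reason, scored, flagged) and output paths, and the whole run is
reproducible from (RunConfig, code version).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .classifier import classify_minutes, evaluate_agreement, train_classifier
from .features import extract_minute_features, split_components
from .glm import AnalysisError, analyze_parameter, build_cohort_table, summarize_by_group
from .scoring import (
    DetectionConfig,
    NoInBedPeriodError,
    OnsetUndefinedError,
    apply_inclusion_criteria,
    detect_in_bed_period,
    score_sleep,
)
from .simulate import CohortConfig, generate_cohort
from .types import ParameterError, SensorConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and subject."""


@dataclass
class RunConfig:
    """Serializable configuration of one reproducible pipeline run."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classifier: dict = field(default_factory=dict)
    train_fraction: float = 0.5
    alpha: float = 0.01
    analyze: bool = True
    analysis_parameters: tuple[str, ...] = ("tst", "se", "waso")
    save_raw: bool = False
    save_intermediate: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["tib_curve"] = {int(k): float(v) for k, v in self.cohort.tib_curve.items()}
        return d

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "tib_curve" in c:
                c["tib_curve"] = {int(k): float(v) for k, v in c["tib_curve"].items()}
            if "age_range" in c:
                c["age_range"] = tuple(c["age_range"])
            d["cohort"] = CohortConfig(**c)
        if "sensor" in d and isinstance(d["sensor"], dict):
            d["sensor"] = SensorConfig(**d["sensor"])
        if "detection" in d and isinstance(d["detection"], dict):
            d["detection"] = DetectionConfig(**d["detection"])
        if "analysis_parameters" in d:
            d["analysis_parameters"] = tuple(d["analysis_parameters"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _effects_to_json(report) -> dict:
    return {
        "parameter": report.parameter,
        "distribution": report.distribution,
        "link": report.link,
        "alpha": report.alpha,
        "interaction_p": report.interaction_p,
        "interaction_significant": report.interaction_significant,
        "path": report.path,
        "main_effects": {k: (None if v != v else float(v)) for k, v in report.main_effects.items()},
        "contrasts": report.contrasts.to_dict(orient="records"),
        "aic_table": report.aic_table.replace([np.inf, -np.inf], None).to_dict(orient="records"),
        "n": report.n,
    }


def run_pipeline(config: RunConfig, out_dir: Path) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    t0 = time.time()

    cohort = replace(config.cohort, seed=config.cohort.seed + config.seed)
    excluded: dict[str, int] = {}
    subjects = []  # (meta, truth, features_df, mean_vgmc)
    n_generated = 0
    stage_times: dict[str, float] = {}

    t = time.time()
    for subj in generate_cohort(cohort, sensor=config.sensor, include_acceleration=True):
        n_generated += 1
        sid = subj.meta.subject_id
        try:
            comps = split_components(subj.accel)
            mvg = float(comps.gc[:, 2].mean())
            decision = apply_inclusion_criteria(
                record=None, meta=subj.meta, mean_vertical_gmc=mvg)
            if not decision.included:
                for reason in decision.reasons:
                    excluded[reason] = excluded.get(reason, 0) + 1
                continue
            feats = extract_minute_features(comps)
            if config.save_raw:
                tio.write_acceleration(subj.accel, out_dir / "records")
            if config.save_intermediate:
                tio.write_truth(subj.truth.posture_per_minute,
                                subj.truth.sleepwake_per_minute,
                                out_dir / "truth" / f"{sid}.csv")
                tio.write_features(feats, out_dir / "features" / f"{sid}.csv")
            subjects.append((subj.meta, subj.truth, feats))
        except (ValueError, RuntimeError) as exc:
            raise PipelineError(f"stage=features subject={sid}: {exc}") from exc
    stage_times["simulate_features"] = time.time() - t

    n_included = len(subjects)
    if n_included < 2:
        raise PipelineError(f"stage=train: only {n_included} included subjects")

    # subject-wise train/apply split for the classifier
    t = time.time()
    n_train = max(2, int(round(config.train_fraction * n_included)))
    train_rows = []
    for meta, truth, feats in subjects[:n_train]:
        df = feats.copy()
        df["state"] = truth.sleepwake_per_minute[: len(df)]
        df["subject_id"] = meta.subject_id
        train_rows.append(df)
    train_df = pd.concat(train_rows, ignore_index=True)
    try:
        model = train_classifier(train_df, hyper=config.classifier, seed=config.seed)
    except ValueError as exc:
        raise PipelineError(f"stage=train: {exc}") from exc
    tio.save_model(model, out_dir / "model.joblib")
    stage_times["train"] = time.time() - t

    t = time.time()
    rows = []
    flags: dict[str, int] = {"no_in_bed_period": 0, "onset_undefined": 0}
    agreements = []
    for meta, truth, feats in subjects:
        sid = meta.subject_id
        predicted = classify_minutes(model, feats)
        if config.save_intermediate:
            tio.write_labels(predicted, out_dir / "labels" / f"{sid}.csv")
        agreements.append(
            evaluate_agreement(predicted.labels[: truth.n_minutes],
                               truth.sleepwake_per_minute[: len(predicted.labels)]).accuracy
        )
        try:
            ibt, gut = detect_in_bed_period(feats, config.detection)
        except NoInBedPeriodError:
            flags["no_in_bed_period"] += 1
            continue
        try:
            params = score_sleep(predicted.labels, ibt, gut, meta=meta)
        except OnsetUndefinedError:
            flags["onset_undefined"] += 1
            continue
        rows.append(tio.params_to_row(meta, params))
    params_path = tio.write_params_table(rows, out_dir / "params.csv")
    stage_times["score"] = time.time() - t

    effects: dict = {}
    summary_path = None
    if config.analyze and rows:
        t = time.time()
        table = build_cohort_table(tio.read_params_table(params_path))
        summary = summarize_by_group(table, by_gender=True)
        summary_path = out_dir / "summary.csv"
        summary.to_csv(summary_path, index=False)
        for parameter in config.analysis_parameters:
            try:
                report = analyze_parameter(table, parameter, alpha=config.alpha)
                effects[parameter] = _effects_to_json(report)
            except (AnalysisError, ValueError) as exc:
                effects[parameter] = {"error": f"{type(exc).__name__}: {exc}"}
        (out_dir / "effects.json").write_text(json.dumps(effects, indent=1))
        stage_times["analyze"] = time.time() - t

    manifest = {
        "seed": config.seed,
        "counts": {
            "generated": n_generated,
            "included": n_included,
            "excluded_by_reason": excluded,
            "excluded_total": int(sum(excluded.values())),
            "scored": len(rows),
            "flagged": flags,
        },
        "classifier": {
            "n_train_subjects": n_train,
            "best_params": getattr(model, "best_params_", None),
            "mean_minutewise_accuracy_pct": float(np.mean(agreements)) if agreements else None,
        },
        "paths": {
            "params": str(params_path),
            "model": str(out_dir / "model.joblib"),
            "effects": str(out_dir / "effects.json") if effects else None,
            "summary": str(summary_path) if summary_path else None,
        },
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
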