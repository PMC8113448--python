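"""Minute-epoch sleep-wake classification and agreement evaluation.

A support vector machine with an RBF kernel maps the per-minute feature
vector (three trunk tilt angles, TPower) to a sleep or wake label.  Sleep
is the positive class throughout, matching the actigraphy convention that
sensitivity measures sleep detection.  Hyperparameters are chosen by
subject-grouped cross-validation on F1 so that minutes from one subject
never appear on both sides of a validation split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, GroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_COLUMNS
from .types import SLEEP, WAKE, InputError, SleepWakeSeries

__all__ = [
    "SleepWakeClassifier",
    "AgreementMetrics",
    "train_classifier",
    "classify_minutes",
    "evaluate_agreement",
]


class SleepWakeClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM over (tilt angles, TPower) minute features.

    Parameters
    ----------
    C_grid, gamma_grid:
        Candidate SVM cost and kernel-width values; the pair with the best
        grouped-CV F1 (sleep positive) is kept.  Single-element grids skip
        the search.
    max_train_samples:
        Upper bound on training minutes; larger inputs are subsampled
        (stratified by class, seeded) to keep the quadratic SVM fit
        tractable on multi-day cohorts.
    cv_splits:
        Folds for the subject-grouped cross-validation.
    """

    def __init__(
        self,
        C_grid: Sequence[float] = (1.0, 10.0),
        gamma_grid: Sequence = ("scale",),
        class_weight: str = "balanced",
        cv_splits: int = 3,
        max_train_samples: int = 4000,
        random_state: int = 0,
    ) -> None:
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.class_weight = class_weight
        self.cv_splits = cv_splits
        self.max_train_samples = max_train_samples
        self.random_state = random_state

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise InputError("X must be 2-dimensional (minutes x features)")
        if X.shape[0] != y.shape[0]:
            raise InputError("X and y lengths differ")
        mask = np.all(np.isfinite(X), axis=1)
        return X, y, mask

    def fit(self, X, y, groups: Optional[np.ndarray] = None):
        """Fit on labelled minutes; ``groups`` are subject identifiers."""
        X, y, finite = self._validate(X, y)
        X, y = X[finite], y[finite]
        if groups is not None:
            groups = np.asarray(groups)[finite]
        classes = np.unique(y)
        if classes.size < 2:
            raise InputError("training set contains a single class")

        rng = np.random.default_rng(self.random_state)
        if X.shape[0] > self.max_train_samples:
            idx = self._stratified_subsample(y, rng)
            X, y = X[idx], y[idx]
            if groups is not None:
                groups = groups[idx]

        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="rbf", class_weight=self.class_weight)),
            ]
        )
        grid = {"svm__C": list(self.C_grid), "svm__gamma": list(self.gamma_grid)}
        n_cands = len(grid["svm__C"]) * len(grid["svm__gamma"])
        if n_cands > 1:
            if groups is not None and np.unique(groups).size >= 2:
                cv = GroupKFold(n_splits=min(self.cv_splits, int(np.unique(groups).size)))
                fit_groups = groups
            else:
                cv = StratifiedKFold(
                    n_splits=self.cv_splits, shuffle=True, random_state=self.random_state
                )
                fit_groups = None
            from sklearn.metrics import f1_score, make_scorer

            # zero_division guards folds where one class is absent
            scorer = make_scorer(f1_score, zero_division=0)
            search = GridSearchCV(pipe, grid, scoring=scorer, cv=cv, n_jobs=1)
            search.fit(X, y, groups=fit_groups)
            self.best_params_ = search.best_params_
            self.cv_results_ = {
                k: v for k, v in search.cv_results_.items() if k in ("params", "mean_test_score")
            }
            self.pipeline_ = search.best_estimator_
        else:
            pipe.set_params(svm__C=grid["svm__C"][0], svm__gamma=grid["svm__gamma"][0])
            pipe.fit(X, y)
            self.best_params_ = {"svm__C": grid["svm__C"][0], "svm__gamma": grid["svm__gamma"][0]}
            self.pipeline_ = pipe
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        scaler: StandardScaler = self.pipeline_.named_steps["scale"]
        self.feature_means_ = scaler.mean_.copy()
        self.feature_scales_ = scaler.scale_.copy()
        self.n_train_minutes_ = X.shape[0]
        self.train_groups_ = None if groups is None else np.unique(groups)
        return self

    def _stratified_subsample(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        keep: list[np.ndarray] = []
        frac = self.max_train_samples / y.size
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            k = max(2, int(round(frac * idx.size)))
            keep.append(rng.choice(idx, size=min(k, idx.size), replace=False))
        return np.sort(np.concatenate(keep))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        finite = np.all(np.isfinite(X), axis=1)
        out = np.full(X.shape[0], WAKE, dtype=int)
        if finite.any():
            out[finite] = self.pipeline_.predict(X[finite])
        return out

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))


def train_classifier(
    features: pd.DataFrame,
    hyper: Optional[dict] = None,
    seed: int = 0,
) -> SleepWakeClassifier:
    """Train from a stacked feature table.

    ``features`` needs the four feature columns plus ``state`` (0/1 labels)
    and ``subject_id`` (grouping for subject-wise cross-validation).
    """
    for col in FEATURE_COLUMNS + ["state", "subject_id"]:
        if col not in features.columns:
            raise InputError(f"features table lacks column '{col}'")
    hyper = dict(hyper or {})
    clf = SleepWakeClassifier(random_state=seed, **hyper)
    clf.fit(
        features[FEATURE_COLUMNS].to_numpy(dtype=float),
        features["state"].to_numpy(dtype=int),
        groups=features["subject_id"].to_numpy(),
    )
    return clf


def classify_minutes(model: SleepWakeClassifier, features: pd.DataFrame) -> SleepWakeSeries:
    """One label per minute; invalid minutes are labelled wake and flagged."""
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    labels = model.predict(X)
    invalid = ~np.all(np.isfinite(X), axis=1)
    if "valid" in features.columns:
        invalid |= ~features["valid"].to_numpy(dtype=bool)
    labels[invalid] = WAKE
    return SleepWakeSeries(labels=labels, source="predicted", invalid_minutes=invalid)


@dataclass(frozen=True)
class AgreementMetrics:
    """Minute-level agreement, in percent, with sleep as the positive class.

    Components with a zero denominator are NaN and named in ``undefined``
    rather than silently reported as 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int
    undefined: tuple[str, ...] = ()


def evaluate_agreement(
    predicted: SleepWakeSeries | np.ndarray,
    truth: SleepWakeSeries | np.ndarray,
) -> AgreementMetrics:
    """Confusion-matrix agreement between predicted and true minute labels."""
    p = predicted.labels if isinstance(predicted, SleepWakeSeries) else np.asarray(predicted, int)
    t = truth.labels if isinstance(truth, SleepWakeSeries) else np.asarray(truth, int)
    if p.size != t.size:
        raise InputError(f"length mismatch: predicted {p.size} vs truth {t.size}")
    if p.size == 0:
        raise InputError("empty label series")

    tp = int(np.sum((p == SLEEP) & (t == SLEEP)))
    tn = int(np.sum((p == WAKE) & (t == WAKE)))
    fp = int(np.sum((p == SLEEP) & (t == WAKE)))
    fn = int(np.sum((p == WAKE) & (t == SLEEP)))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    accuracy = 100.0 * (tp + tn) / p.size
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    return AgreementMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        undefined=tuple(undefined),
    )
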