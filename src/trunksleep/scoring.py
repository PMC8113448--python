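"""In-bed period detection, sleep-parameter scoring and inclusion screening.

The in-bed block (bedtime IBT to get-up time GUT) is detected from
minute-level posture and activity features: a minute counts toward the
block when the trunk is tilted past a lying threshold and the local
activity variance (TPower) is below a rest threshold; the block is the
longest run of such minutes tolerating short interruptions.

Scoring then follows standard actigraphic definitions: sleep onset is the
start of the first 10 consecutive sleep-labelled minutes at or after IBT;
SL = onset - IBT; WASO = wake minutes from onset to GUT; TIB = GUT - IBT;
TST = TIB - SL - WASO; SE = 100 * TST / TIB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    InputError,
    SLEEP,
    WAKE,
    AccelRecord,
    SleepParameters,
    SleepWakeSeries,
    SubjectMeta,
)

__all__ = [
    "DetectionConfig",
    "NoInBedPeriodError",
    "OnsetUndefinedError",
    "InclusionDecision",
    "find_longest_tolerant_run",
    "detect_in_bed_period",
    "score_sleep",
    "apply_inclusion_criteria",
]

ONSET_RUN_MINUTES = 10  # consecutive sleep minutes defining sleep onset


class NoInBedPeriodError(ValueError):
    """No qualifying lying-and-rest block was found in the record."""


class OnsetUndefinedError(ValueError):
    """No run of 10 consecutive sleep minutes exists before get-up time."""


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for IBT/GUT detection.

    ``rest_threshold=None`` selects the threshold per record by a 2-class
    Otsu split of the nightly TPower distribution, which adapts to the
    record's own activity scale.
    """

    lying_angle_deg: float = 60.0
    rest_threshold: Optional[float] = None
    gap_tolerance_min: int = 10
    min_duration_min: int = 120


def find_longest_tolerant_run(indicator: np.ndarray, gap_tolerance: int) -> Optional[tuple[int, int]]:
    """Longest half-open span [s, e) starting and ending on True minutes in
    which every interior run of False minutes is at most ``gap_tolerance``
    long.  Ties break toward the earliest span.  Returns None if the
    indicator has no True entry.
    """
    indicator = np.asarray(indicator, dtype=bool)
    if indicator.size == 0 or not indicator.any():
        return None
    # maximal runs of True as (start, end) half-open
    padded = np.diff(np.concatenate(([0], indicator.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    # merge runs separated by gaps <= tolerance
    best = (int(starts[0]), int(ends[0]))
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s - cur_e <= gap_tolerance:
            cur_e = int(e)
        else:
            cur_s, cur_e = int(s), int(e)
        if cur_e - cur_s > best[1] - best[0]:
            best = (cur_s, cur_e)
    return best


def detect_in_bed_period(
    features: pd.DataFrame, config: DetectionConfig = DetectionConfig()
) -> tuple[int, int]:
    """Detect (ibt_minute, gut_minute) from a per-minute feature table.

    ``features`` must carry ``tilt_vertical_deg``, ``tpower`` and ``valid``
    columns (as produced by :func:`trunksleep.features.extract_minute_features`).
    Raises :class:`NoInBedPeriodError` with diagnostics when no block
    qualifies.
    """
    required = {"tilt_vertical_deg", "tpower", "valid"}
    missing = required - set(features.columns)
    if missing:
        raise InputError(f"feature table lacks columns: {sorted(missing)}")

    tilt = features["tilt_vertical_deg"].to_numpy(dtype=float)
    tpow = features["tpower"].to_numpy(dtype=float)
    valid = features["valid"].to_numpy(dtype=bool)

    threshold = config.rest_threshold
    if threshold is None:
        vals = tpow[valid & np.isfinite(tpow)]
        if vals.size < 2 or np.ptp(vals) == 0:
            raise NoInBedPeriodError(
                "cannot derive a rest threshold: TPower is degenerate "
                f"({vals.size} valid minutes)")
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(vals))

    lying = valid & (tilt > config.lying_angle_deg)
    rest = valid & (tpow < threshold)
    indicator = lying & rest

    span = find_longest_tolerant_run(indicator, config.gap_tolerance_min)
    if span is None:
        raise NoInBedPeriodError(
            f"no lying-and-rest minutes (lying: {int(lying.sum())}, "
            f"rest: {int(rest.sum())}, threshold: {threshold:.3g})")
    ibt, gut = span
    if gut - ibt < config.min_duration_min:
        raise NoInBedPeriodError(
            f"longest candidate block spans {gut - ibt} min "
            f"< min_duration_min={config.min_duration_min}")
    return ibt, gut


def _find_onset(labels: np.ndarray, ibt: int, gut: int, run: int) -> Optional[int]:
    sleep = labels[ibt:gut] == SLEEP
    if sleep.size < run:
        return None
    window = np.convolve(sleep.astype(int), np.ones(run, dtype=int), mode="valid")
    hits = np.flatnonzero(window == run)
    if hits.size == 0:
        return None
    return ibt + int(hits[0])


def score_sleep(
    labels: np.ndarray | SleepWakeSeries | Sequence[int],
    ibt_minute: int,
    gut_minute: int,
    meta: Optional[SubjectMeta] = None,
    onset_run: int = ONSET_RUN_MINUTES,
) -> SleepParameters:
    """Score the seven sleep parameters from minute labels and bed times.

    Raises :class:`OnsetUndefinedError` when no qualifying onset run exists
    in [ibt, gut); such records are excluded from parameter tables rather
    than scored with a degenerate latency.
    """
    if isinstance(labels, SleepWakeSeries):
        labels = labels.labels
    labels = np.asarray(labels, dtype=int)
    if not (0 <= ibt_minute < gut_minute <= labels.size):
        raise InputError(
            f"require 0 <= ibt ({ibt_minute}) < gut ({gut_minute}) <= "
            f"n_minutes ({labels.size})")

    onset = _find_onset(labels, ibt_minute, gut_minute, onset_run)
    if onset is None:
        raise OnsetUndefinedError(
            f"no {onset_run}-min consecutive sleep run in [{ibt_minute}, {gut_minute})")

    tib = gut_minute - ibt_minute
    sl = onset - ibt_minute
    waso = int(np.sum(labels[onset:gut_minute] == WAKE))
    tst = tib - sl - waso
    se = 100.0 * tst / tib
    return SleepParameters(
        ibt_minute=int(ibt_minute),
        gut_minute=int(gut_minute),
        tib=int(tib),
        sl=int(sl),
        waso=waso,
        tst=int(tst),
        se=float(se),
        recording_start=meta.recording_start if meta is not None else None,
    )


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    reasons: tuple[str, ...]


def apply_inclusion_criteria(
    record: AccelRecord | None = None,
    meta: Optional[SubjectMeta] = None,
    mean_vertical_gmc: Optional[float] = None,
    noise_beat_threshold: float = 0.10,
) -> InclusionDecision:
    """Screen one recording against the cohort inclusion criteria.

    Included iff recording duration > 20 h, 10 <= age <= 89, noise-beat
    fraction < 0.10, and the whole-record mean vertical gravitational
    component > -1.0 g (strict; a recording pinned at -1 g indicates a
    device left unworn or worn incorrectly).  ``reasons`` lists every
    failed criterion.  ``mean_vertical_gmc`` may be supplied precomputed;
    otherwise it is derived from ``record``.
    """
    if meta is None:
        if record is None:
            return InclusionDecision(False, ("missing:metadata",))
        meta = record.meta

    reasons: list[str] = []
    if meta.recording_duration is None:
        reasons.append("missing:recording_duration")
    elif not meta.recording_duration > 20.0:
        reasons.append("criterion_1_duration")
    if meta.age is None:
        reasons.append("missing:age")
    elif not (10 <= meta.age <= 89):
        reasons.append("criterion_2_age")
    if meta.noise_beat_fraction is None:
        reasons.append("missing:noise_beat_fraction")
    elif not meta.noise_beat_fraction < noise_beat_threshold:
        reasons.append("criterion_3_noise_beats")

    if mean_vertical_gmc is None and record is not None:
        from .features import mean_vertical_gmc as _mvg

        mean_vertical_gmc = _mvg(record)
    if mean_vertical_gmc is None:
        reasons.append("missing:vertical_gmc")
    elif not mean_vertical_gmc > -1.0:
        reasons.append("criterion_4_vertical_gmc")

    return InclusionDecision(included=not reasons, reasons=tuple(reasons))
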