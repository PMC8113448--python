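"""Core domain types for trunk-accelerometry sleep assessment.

Axis convention: tri-axial samples are ordered (medio-lateral,
antero-posterior, vertical) in units of g.  Upright posture places the
gravitational component near (0, 0, -1) g; supine lying moves gravity into
the antero-posterior axis, so the vertical component is near 0 g.

Minute indexing is half-open and counted from the start of the recording;
clock times are derived from ``SubjectMeta.recording_start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

#: integer label codes for minute-epoch sleep/wake series
WAKE: int = 0
SLEEP: int = 1

#: posture codes in truth schedules
UPRIGHT: int = 0
LYING: int = 1

MINUTES_PER_DAY = 1440


class ParameterError(ValueError):
    """A configuration value produced an impossible schedule or design."""


class InputError(ValueError):
    """An input record or table violates a precondition."""


@dataclass(frozen=True)
class SensorConfig:
    """Accelerometer front-end: Holter-style tri-axial sensor.

    Defaults follow the ambulatory Holter accelerometer used for trunk
    actigraphy: 31.25 Hz sampling, +/-3 g full scale, 10-bit quantization.
    ``noise_sd`` is the per-axis Gaussian sensor-noise standard deviation.
    """

    sampling_rate: float = 31.25
    range_g: float = 3.0
    resolution_bits: int = 10
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.resolution_bits < 1:
            raise ParameterError("resolution_bits must be >= 1")
        if self.range_g <= 0:
            raise ParameterError("range_g must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def quantization_step(self) -> float:
        """LSB size in g: full span divided by the number of codes."""
        return 2.0 * self.range_g / 2 ** self.resolution_bits


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata accompanying one 24-h recording.

    ``noise_beat_fraction`` is a simulated stand-in for the ECG noise-beat
    screening criterion; no ECG signal exists in this package.
    """

    subject_id: str
    age: int
    gender: str = "unknown"  # {male, female, unknown}
    recording_month: int = 6
    recording_start: datetime = datetime(2020, 6, 15, 9, 0)
    recording_duration: float = 24.0  # hours
    noise_beat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.age, (int, np.integer)) and self.age >= 0):
            raise ParameterError("age must be a non-negative integer")
        if self.gender not in ("male", "female", "unknown"):
            raise ParameterError("gender must be male, female or unknown")
        if not 1 <= self.recording_month <= 12:
            raise ParameterError("recording_month must be in 1..12")
        if self.recording_duration <= 0:
            raise ParameterError("recording_duration must be > 0")
        if not 0.0 <= self.noise_beat_fraction <= 1.0:
            raise ParameterError("noise_beat_fraction must be in [0, 1]")

    @property
    def n_minutes(self) -> int:
        return int(np.floor(self.recording_duration * 60))

    def minute_to_clock(self, minute: int) -> datetime:
        return self.recording_start + timedelta(minutes=int(minute))

    def minute_to_hhmm(self, minute: int) -> str:
        return self.minute_to_clock(minute).strftime("%H:%M")


@dataclass
class SleepParameters:
    """The seven nightly sleep parameters for one subject-night.

    ``ibt_minute``/``gut_minute`` index minutes from recording start with a
    half-open in-bed interval [ibt, gut).  Invariants enforced on
    construction: tib = gut - ibt > 0, tst = tib - sl - waso,
    se = 100 * tst / tib, sl >= 0, waso >= 0, sl + waso <= tib.
    """

    ibt_minute: int
    gut_minute: int
    tib: int
    sl: int
    waso: int
    tst: int
    se: float
    recording_start: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.tib != self.gut_minute - self.ibt_minute or self.tib <= 0:
            raise ParameterError("tib must equal gut - ibt and be > 0")
        if self.sl < 0 or self.waso < 0:
            raise ParameterError("sl and waso must be >= 0")
        if self.sl + self.waso > self.tib:
            raise ParameterError("sl + waso must not exceed tib")
        if self.tst != self.tib - self.sl - self.waso:
            raise ParameterError("tst must equal tib - sl - waso")
        if abs(self.se - 100.0 * self.tst / self.tib) > 1e-9:
            raise ParameterError("se must equal 100 * tst / tib")

    def _clock(self, minute: int) -> Optional[str]:
        if self.recording_start is None:
            return None
        return (self.recording_start + timedelta(minutes=int(minute))).strftime("%H:%M")

    @property
    def ibt_hhmm(self) -> Optional[str]:
        return self._clock(self.ibt_minute)

    @property
    def gut_hhmm(self) -> Optional[str]:
        return self._clock(self.gut_minute)

    def minutes_from_midnight(self, minute: int) -> Optional[int]:
        if self.recording_start is None:
            return None
        clk = self.recording_start + timedelta(minutes=int(minute))
        return clk.hour * 60 + clk.minute


@dataclass
class TruthSchedule:
    """Ground-truth minute grid for one simulated subject.

    Real cohort recordings carry no such annotation; the simulator provides
    it so every downstream stage can be validated against known truth.
    """

    posture_per_minute: np.ndarray  # int codes {UPRIGHT, LYING}
    sleepwake_per_minute: np.ndarray  # int codes {WAKE, SLEEP}
    activity_intensity_per_minute: np.ndarray  # g^2 bodily-motion variance
    true_params: Optional[SleepParameters] = None  # None for schedules with no night

    def __post_init__(self) -> None:
        n = len(self.posture_per_minute)
        if not (len(self.sleepwake_per_minute) == n == len(self.activity_intensity_per_minute)):
            raise ParameterError("all per-minute sequences must share one length")
        sleeping = self.sleepwake_per_minute == SLEEP
        if np.any(sleeping & (self.posture_per_minute != LYING)):
            raise ParameterError("sleep labels may only occur in lying posture")

    @property
    def n_minutes(self) -> int:
        return len(self.posture_per_minute)


@dataclass
class AccelRecord:
    """Raw tri-axial acceleration series with sensor config and metadata."""

    samples: np.ndarray  # shape (n, 3), g units, columns (ml, ap, vertical)
    sensor: SensorConfig
    meta: SubjectMeta

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InputError("samples must have shape (n, 3)")
        if self.samples.shape[0] < 1:
            raise InputError("record must contain at least one sample")
        if np.any(np.abs(self.samples) > self.sensor.range_g + 1e-9):
            raise InputError("samples exceed the sensor range")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sensor.sampling_rate


@dataclass
class ComponentSeries:
    """Gravitational (gc) and bodily-motion (bmc) decomposition.

    Invariant: ``gc + bmc`` reconstructs the source samples exactly.
    """

    gc: np.ndarray
    bmc: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.gc.shape != self.bmc.shape:
            raise InputError("gc and bmc must share a shape")


@dataclass
class SleepWakeSeries:
    """Minute-by-minute sleep/wake labels, predicted or ground truth."""

    labels: np.ndarray  # int codes {WAKE, SLEEP}
    minute_offset: int = 0
    source: str = "predicted"  # {truth, predicted}
    invalid_minutes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size < 1:
            raise InputError("label series must be non-empty")
        if not np.all(np.isin(self.labels, (WAKE, SLEEP))):
            raise InputError("labels must be WAKE (0) or SLEEP (1)")
        if self.invalid_minutes.size == 0:
            self.invalid_minutes = np.zeros(self.labels.size, dtype=bool)

    def __len__(self) -> int:
        return self.labels.size


def labels_to_str(labels: Sequence[int]) -> list[str]:
    return ["S" if x == SLEEP else "W" for x in labels]


def labels_from_str(tokens: Sequence[str]) -> np.ndarray:
    mapping = {"S": SLEEP, "W": WAKE}
    try:
        return np.array([mapping[t.strip().upper()] for t in tokens], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise InputError(f"unknown sleep/wake token {exc}") from exc
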