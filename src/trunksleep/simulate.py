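"""Synthetic cohort generator emulating 24-h Holter trunk accelerometry.

The generator produces, per subject, (1) a minute-resolution ground-truth
schedule — posture, sleep/wake state and bodily-motion intensity — with a
single nocturnal in-bed block, and (2) the raw tri-axial acceleration
signal that a trunk-worn Holter accelerometer would record for that
schedule (gravity projection by posture, bodily-motion noise, sensor noise,
clipping and quantization).

Population structure is configurable through :class:`CohortConfig`: the
default timing and quality effects (bedtime advancing ~20 min per decade of
age after the 20s, get-up time advancing ~15 min per decade, wake after
sleep onset growing ~4 min per decade above age 30, women sleeping ~31 min
less than men) reproduce the age/gender gradients reported for large
Japanese Holter cohorts, so a simulated cohort exercises the same
statistical analysis a real one would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterator, Optional

import numpy as np

from .scoring import score_sleep
from .types import (
    LYING,
    MINUTES_PER_DAY,
    SLEEP,
    UPRIGHT,
    WAKE,
    AccelRecord,
    ParameterError,
    SensorConfig,
    SubjectMeta,
    TruthSchedule,
)

__all__ = [
    "CohortConfig",
    "CohortSubject",
    "generate_subject_truth",
    "synthesize_acceleration",
    "generate_cohort",
]

_REFERENCE_AGE = 25.0  # centre of the 20s group, the latest-timed group


def _u_shape_default() -> dict[int, float]:
    # Get-up-time deviations (minutes) per decade group 1 (10s) .. 8 (80s).
    # Added on top of the linear timing trends they bend the group-mean TIB
    # into a U shape with its nadir in the 40s group.
    return {1: 30.0, 2: 0.0, 3: -25.0, 4: -40.0, 5: -30.0, 6: -15.0, 7: 0.0, 8: 15.0}


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters for a simulated cohort.

    Timing is parameterized on the minutes-from-midnight scale.  Age slopes
    are expressed per decade of age and apply above the stated pivot ages;
    below them, timing is flat at the 20s reference (the latest-timed
    group).  ``gender_tst_gap`` is female minus male total sleep time and is
    implemented as a later female bedtime with an unchanged get-up time.
    """

    n_subjects: int = 100
    age_range: tuple[int, int] = (10, 89)
    gender_ratio: float = 0.5  # proportion female

    # group-level timing (minutes from midnight; 23:34 and 07:31)
    ibt_ref: float = 23 * 60 + 34.0
    gut_ref: float = 7 * 60 + 31.0
    ibt_advance_per_decade: float = 20.1  # min earlier per decade above age 20
    gut_advance_per_decade: float = 14.9
    tib_curve: dict[int, float] = field(default_factory=_u_shape_default)

    # sleep quality
    sl_mean: float = 15.0  # min; gamma-distributed latency
    sl_shape: float = 2.0
    waso_base: float = 25.0  # min at and below age 30
    waso_slope_per_decade: float = 4.1  # min per decade above age 30
    waso_shape: float = 2.0
    gender_tst_gap: float = -30.7  # min, female minus male

    # between-subject heterogeneity (Gaussian intercepts, minutes)
    ibt_sd: float = 40.0
    gut_sd: float = 30.0

    # within-night wake bout structure (semi-Markov, gamma bout lengths)
    wake_bout_mean: float = 4.0
    wake_bout_shape: float = 1.5

    # bodily-motion variance per axis (g^2) by behavioural state
    day_intensity: float = 2.0e-2
    inbed_wake_intensity: float = 5.0e-4  # quiet wakefulness: far below ambulation
    sleep_intensity: float = 1.0e-5
    intensity_jitter_sd: float = 0.3  # lognormal sigma on per-minute intensity

    # supine orientation scatter (degrees, truncated at 2 sd)
    lying_tilt_sd: float = 4.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not 0.0 <= self.gender_ratio <= 1.0:
            raise ParameterError("gender_ratio must be in [0, 1]")
        lo, hi = self.age_range
        if not (0 <= lo <= hi):
            raise ParameterError("age_range must satisfy 0 <= low <= high")
        for name in ("sl_mean", "sl_shape", "waso_base", "waso_shape",
                     "wake_bout_mean", "wake_bout_shape"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class CohortSubject:
    """One simulated subject: metadata, ground truth, optional raw signal."""

    meta: SubjectMeta
    truth: TruthSchedule
    accel: Optional[AccelRecord] = None


def _decades_above(age: float, pivot: float) -> float:
    return max(0.0, age - pivot) / 10.0


def _trunc_normal(rng: np.random.Generator, sd: float, cap_sd: float = 3.0) -> float:
    if sd == 0:
        return 0.0
    x = rng.normal(0.0, sd)
    return float(np.clip(x, -cap_sd * sd, cap_sd * sd))


def _rounded_gamma(rng: np.random.Generator, mean: float, shape: float) -> int:
    if mean <= 0:
        return 0
    return int(round(rng.gamma(shape, mean / shape)))


def mean_timing(age: float, gender: str, config: CohortConfig) -> tuple[float, float]:
    """Population-mean bedtime and get-up time (minutes from midnight)."""
    ibt = config.ibt_ref - config.ibt_advance_per_decade * _decades_above(age, _REFERENCE_AGE)
    gut = config.gut_ref - config.gut_advance_per_decade * _decades_above(age, _REFERENCE_AGE)
    decade = int(np.clip(age // 10, 1, 8))
    gut += config.tib_curve.get(decade, 0.0)
    if gender == "female":
        # a later bedtime with an unchanged rise time shortens TIB and TST
        ibt -= config.gender_tst_gap
    return ibt, gut


def generate_subject_truth(meta: SubjectMeta, config: CohortConfig, seed: int) -> TruthSchedule:
    """Draw one subject's ground-truth schedule.

    The night consists of one contiguous in-bed block whose timing follows
    the configured age/gender effects plus Gaussian subject-level noise.
    Inside the block, latency minutes are wake, sleep onset opens a run of
    at least 10 sleep minutes, and subsequent wake returns as gamma-length
    bouts whose total equals the drawn WASO.  Daytime minutes are upright
    wake with high bodily-motion intensity.
    """
    rng = np.random.default_rng(seed)
    n_min = meta.n_minutes

    ibt_mfm, gut_mfm = mean_timing(meta.age, meta.gender, config)
    ibt_mfm += _trunc_normal(rng, config.ibt_sd)
    gut_mfm += _trunc_normal(rng, config.gut_sd)

    start_mfm = meta.recording_start.hour * 60 + meta.recording_start.minute
    ibt = int(round(ibt_mfm - start_mfm)) % MINUTES_PER_DAY
    tib = int(round(gut_mfm - ibt_mfm)) % MINUTES_PER_DAY
    if tib <= 0:
        raise ParameterError(
            "configured timing effects produced non-positive TIB "
            "(check ibt_advance_per_decade/gut_advance_per_decade/tib_curve)")
    gut = ibt + tib
    if gut > n_min:
        raise ParameterError(
            "in-bed block extends past the recording end; increase "
            "recording_duration or adjust ibt_ref/gut_ref")

    sl = _rounded_gamma(rng, config.sl_mean, config.sl_shape)
    waso_mean = config.waso_base + config.waso_slope_per_decade * _decades_above(meta.age, 30.0)
    waso = _rounded_gamma(rng, waso_mean, config.waso_shape)

    # feasibility: onset run of 10 sleep minutes plus margin must fit
    sl = min(sl, max(0, tib - 40))
    waso = min(waso, max(0, tib - sl - 30))

    state = np.full(n_min, WAKE, dtype=int)
    posture = np.full(n_min, UPRIGHT, dtype=int)
    posture[ibt:gut] = LYING

    onset = ibt + sl
    night = np.full(tib - sl, SLEEP, dtype=int)  # minutes [onset, gut)
    if waso > 0:
        night[:] = SLEEP
        bouts: list[int] = []
        remaining = waso
        while remaining > 0:
            b = max(1, _rounded_gamma(rng, config.wake_bout_mean, config.wake_bout_shape))
            b = min(b, remaining)
            bouts.append(b)
            remaining -= b
        sleep_total = (tib - sl) - waso
        # gaps of sleep around the k wake bouts; the first must hold the
        # 10-min onset run, interior gaps at least 1 min
        while len(bouts) > 1 and sleep_total < 10 + (len(bouts) - 1):
            bouts[-2] += bouts[-1]
            bouts.pop()
        k = len(bouts)
        base = np.array([10] + [1] * (k - 1) + [0], dtype=int)
        extra = rng.multinomial(sleep_total - int(base.sum()), np.full(k + 1, 1.0 / (k + 1)))
        gaps = base + extra
        seq: list[np.ndarray] = []
        for i in range(k):
            seq.append(np.full(gaps[i], SLEEP, dtype=int))
            seq.append(np.full(bouts[i], WAKE, dtype=int))
        seq.append(np.full(gaps[k], SLEEP, dtype=int))
        night = np.concatenate(seq)
    state[onset:gut] = night

    jitter = np.exp(rng.normal(0.0, config.intensity_jitter_sd, size=n_min))
    base_int = np.full(n_min, config.day_intensity)
    base_int[ibt:gut] = np.where(state[ibt:gut] == SLEEP,
                                 config.sleep_intensity, config.inbed_wake_intensity)
    intensity = base_int * jitter

    true_params = score_sleep(state, ibt, gut, meta=meta)
    return TruthSchedule(
        posture_per_minute=posture,
        sleepwake_per_minute=state,
        activity_intensity_per_minute=intensity,
        true_params=true_params,
    )


def _lying_gravity(rng: np.random.Generator, tilt_sd_deg: float) -> np.ndarray:
    """Supine gravity direction with a small per-subject random tilt."""
    cap = 2.0 * tilt_sd_deg
    a = np.deg2rad(np.clip(rng.normal(0.0, tilt_sd_deg), -cap, cap))  # toward vertical
    b = np.deg2rad(np.clip(rng.normal(0.0, tilt_sd_deg), -cap, cap))  # toward medio-lateral
    v = np.array([np.sin(b), -np.cos(a) * np.cos(b), np.sin(a)])
    return v / np.linalg.norm(v)


def synthesize_acceleration(
    schedule: TruthSchedule,
    sensor: SensorConfig = SensorConfig(),
    seed: int = 0,
    meta: Optional[SubjectMeta] = None,
    lying_tilt_sd: float = 4.0,
) -> AccelRecord:
    """Render a truth schedule into a raw tri-axial acceleration record.

    Per sample: gravity projection set by posture (upright: vertical axis at
    -1 g; lying: gravity in the antero-posterior axis) plus zero-mean
    Gaussian bodily motion with the schedule's per-minute variance per axis,
    plus sensor noise, then clipped to the sensor range and quantized to the
    sensor resolution.
    """
    samples = _synthesize_samples(schedule, sensor, seed, lying_tilt_sd)
    if meta is None:
        meta = SubjectMeta(
            subject_id="synthetic",
            age=40,
            recording_duration=schedule.n_minutes / 60.0,
        )
    return AccelRecord(samples=samples, sensor=sensor, meta=meta)


def _synthesize_samples(
    schedule: TruthSchedule,
    sensor: SensorConfig,
    seed: int,
    lying_tilt_sd: float,
) -> np.ndarray:
    if schedule.n_minutes == 0:
        raise ParameterError("schedule is empty")
    rng = np.random.default_rng(seed)
    spm = int(round(60 * sensor.sampling_rate))  # samples per minute
    n_min = schedule.n_minutes
    n = n_min * spm

    g_up = np.array([0.0, 0.0, -1.0])
    g_ly = _lying_gravity(rng, lying_tilt_sd)
    grav_min = np.where(
        (schedule.posture_per_minute == LYING)[:, None], g_ly[None, :], g_up[None, :]
    )
    x = np.repeat(grav_min, spm, axis=0)

    sd_min = np.sqrt(schedule.activity_intensity_per_minute)
    sd = np.repeat(sd_min, spm)
    x += rng.standard_normal((n, 3)) * sd[:, None]
    if sensor.noise_sd > 0:
        x += rng.standard_normal((n, 3)) * sensor.noise_sd

    np.clip(x, -sensor.range_g, sensor.range_g, out=x)
    q = sensor.quantization_step
    np.round(x / q, out=x)
    x *= q
    np.clip(x, -sensor.range_g, sensor.range_g, out=x)
    return x


def _draw_meta(rng: np.random.Generator, i: int, config: CohortConfig) -> SubjectMeta:
    lo, hi = config.age_range
    age = int(rng.integers(lo, hi + 1))
    gender = "female" if rng.random() < config.gender_ratio else "male"
    month = int(rng.integers(1, 13))
    # late-morning clinic fit: a 24-h record then spans the entire night
    # even for the latest bedtimes and latest morning rises
    start_minute = int(rng.integers(10 * 60, 12 * 60))
    start = datetime(2020, month, 15, start_minute // 60, start_minute % 60)
    noise_frac = float(rng.beta(1.0, 60.0))
    return SubjectMeta(
        subject_id=f"S{i:05d}",
        age=age,
        gender=gender,
        recording_month=month,
        recording_start=start,
        recording_duration=24.0,
        noise_beat_fraction=noise_frac,
    )


def generate_cohort(
    config: CohortConfig,
    sensor: SensorConfig = SensorConfig(),
    include_acceleration: bool = True,
) -> Iterator[CohortSubject]:
    """Yield ``config.n_subjects`` independent subjects.

    Ages, genders, months and start times are drawn from ``config``;
    per-subject seeds are derived deterministically from ``config.seed`` so
    two cohorts built from the same config are identical.  Subjects are
    yielded lazily because raw 24-h signals are large; pass
    ``include_acceleration=False`` when only truth schedules are needed.
    """
    if config.n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    master = np.random.default_rng(config.seed)
    metas = [_draw_meta(master, i, config) for i in range(config.n_subjects)]
    seeds = master.integers(0, 2**31 - 1, size=2 * config.n_subjects)
    for i, meta in enumerate(metas):
        truth = generate_subject_truth(meta, config, int(seeds[2 * i]))
        accel = None
        if include_acceleration:
            accel = synthesize_acceleration(
                truth, sensor, int(seeds[2 * i + 1]), meta=meta,
                lying_tilt_sd=config.lying_tilt_sd,
            )
        yield CohortSubject(meta=meta, truth=truth, accel=accel)
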