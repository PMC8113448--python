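"""Gravitational/bodily-motion decomposition and per-minute features.

Tri-axial trunk acceleration mixes two physically distinct signals: a
slow-varying gravitational component (GC) whose per-axis projection encodes
upper-body posture, and a fast-varying bodily-motion component (BMC)
produced by physical activity.  A zero-phase low-pass filter separates
them; the residual is the BMC, so ``gc + bmc`` reconstructs the input
exactly by construction.

From each non-overlapping 1-min window two kinds of features are computed:

* trunk tilt angles — ``arccos(-mean_gc_axis / ||mean_gc||)`` per axis, in
  degrees, so an upright trunk gives a vertical tilt of 0 deg and a
  horizontal trunk 90 deg;
* TPower — ``log10`` of the within-window total variance of the BMC (the
  trace of its covariance, i.e. the summed per-axis variances), floored at
  a small epsilon.  The trace is invariant under sensor rotation, so the
  feature measures movement intensity irrespective of orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import AccelRecord, ComponentSeries, InputError

__all__ = [
    "DEFAULT_CUTOFF_HZ",
    "TPOWER_FLOOR",
    "split_components",
    "extract_minute_features",
    "mean_vertical_gmc",
    "MinuteFeatureExtractor",
    "FEATURE_COLUMNS",
]

DEFAULT_CUTOFF_HZ = 0.3  # keeps postural transitions, rejects gait/movement
TPOWER_FLOOR = 1e-6  # g^2 variance floor inside the log
MIN_GC_NORM = 0.2  # g; below this a window is a sensor fault, flagged invalid

FEATURE_COLUMNS = ["tilt_vertical_deg", "tilt_ml_deg", "tilt_ap_deg", "tpower"]


def _design_lowpass(cutoff: float, fs: float):
    if not 0 < cutoff < fs / 2:
        raise InputError(f"cutoff {cutoff} Hz must lie in (0, fs/2={fs / 2})")
    return signal.butter(4, cutoff, btype="low", fs=fs, output="sos")


def split_components(record: AccelRecord, cutoff: float = DEFAULT_CUTOFF_HZ) -> ComponentSeries:
    """Separate a record into gravitational and bodily-motion components.

    The GC is the zero-phase 4th-order Butterworth low-pass of each axis at
    ``cutoff``; the BMC is the per-sample residual, so reconstruction is
    exact.  Records shorter than the filter warm-up are rejected.
    """
    fs = record.sensor.sampling_rate
    sos = _design_lowpass(cutoff, fs)
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if record.n_samples <= padlen:
        raise InputError(
            f"record has {record.n_samples} samples; the zero-phase filter "
            f"needs more than {padlen}")
    gc = signal.sosfiltfilt(sos, record.samples, axis=0)
    bmc = record.samples - gc
    return ComponentSeries(gc=gc, bmc=bmc, sampling_rate=fs)


def extract_minute_features(
    components: ComponentSeries,
    eps: float = TPOWER_FLOOR,
    min_gc_norm: float = MIN_GC_NORM,
) -> pd.DataFrame:
    """Per-minute tilt angles and TPower from a component decomposition.

    Windows are aligned to the record start and non-overlapping; a trailing
    partial window is discarded.  Windows whose mean GC magnitude falls
    below ``min_gc_norm`` (sensor fault) are kept but flagged invalid with
    NaN tilt angles, never silently dropped.

    Returns a DataFrame with columns ``minute``, the tilt angles (deg),
    ``tpower``, ``valid`` and the per-axis mean GC.
    """
    window = int(round(60 * components.sampling_rate))
    n = components.gc.shape[0]
    n_win = n // window
    if n_win < 1:
        raise InputError(f"need at least one full 1-min window ({window} samples)")

    gc = components.gc[: n_win * window].reshape(n_win, window, 3)
    bmc = components.bmc[: n_win * window].reshape(n_win, window, 3)

    mean_gc = gc.mean(axis=1)  # (n_win, 3)
    norm = np.linalg.norm(mean_gc, axis=1)
    valid = norm >= min_gc_norm

    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.clip(-mean_gc / norm[:, None], -1.0, 1.0)
        tilt = np.degrees(np.arccos(cosines))
    tilt[~valid] = np.nan

    # total variance: trace of the within-window BMC covariance
    total_var = bmc.var(axis=1).sum(axis=1)  # (n_win,)
    tpower = np.log10(total_var + eps)

    return pd.DataFrame(
        {
            "minute": np.arange(n_win),
            "tilt_vertical_deg": tilt[:, 2],
            "tilt_ml_deg": tilt[:, 0],
            "tilt_ap_deg": tilt[:, 1],
            "tpower": tpower,
            "valid": valid,
            "mean_gc_ml": mean_gc[:, 0],
            "mean_gc_ap": mean_gc[:, 1],
            "mean_gc_vertical": mean_gc[:, 2],
        }
    )


def mean_vertical_gmc(record: AccelRecord, cutoff: float = DEFAULT_CUTOFF_HZ) -> float:
    """Whole-record mean of the vertical gravitational component, in g.

    Near -1 g for a subject upright throughout; near 0 g when lying.  Used
    by the inclusion screen: a mean pinned at -1 g flags a device that was
    never worn in a varied posture.
    """
    if record.n_samples < 1:
        raise InputError("record is empty")
    comps = split_components(record, cutoff=cutoff)
    return float(comps.gc[:, 2].mean())


class MinuteFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: AccelRecord -> per-minute feature table.

    Composes with scikit-learn pipelines; ``fit`` records nothing beyond
    marking the transformer fitted.
    """

    def __init__(
        self,
        cutoff_hz: float = DEFAULT_CUTOFF_HZ,
        eps: float = TPOWER_FLOOR,
        min_gc_norm: float = MIN_GC_NORM,
    ) -> None:
        self.cutoff_hz = cutoff_hz
        self.eps = eps
        self.min_gc_norm = min_gc_norm

    def fit(self, X=None, y=None):
        self.n_features_in_ = 3
        return self

    def transform(self, X: AccelRecord) -> pd.DataFrame:
        comps = split_components(X, cutoff=self.cutoff_hz)
        return extract_minute_features(comps, eps=self.eps, min_gc_norm=self.min_gc_norm)
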