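"""Sleep-parameter scoring, in-bed detection and inclusion-screen tests,
each against a brute-force oracle where the operation is combinatorial."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trunksleep as ts
from trunksleep.scoring import (
    DetectionConfig,
    find_longest_tolerant_run,
    apply_inclusion_criteria,
)
from trunksleep.types import SLEEP, WAKE, labels_from_str


# --- brute-force oracles -----------------------------------------------------

def oracle_longest_tolerant_run(ind, tol):
    """Enumerate all spans that start and end on True with interior False
    runs <= tol; return the longest (earliest on ties)."""
    true_idx = [i for i, v in enumerate(ind) if v]
    if not true_idx:
        return None
    best = None
    for i in true_idx:
        for j in true_idx:
            if j < i:
                continue
            ok, gap = True, 0
            for k in range(i, j + 1):
                if ind[k]:
                    gap = 0
                else:
                    gap += 1
                    if gap > tol:
                        ok = False
                        break
            if ok:
                span = (i, j + 1)
                if best is None or span[1] - span[0] > best[1] - best[0]:
                    best = span
    return best


def oracle_score(labels, ibt, gut, run=10):
    """Direct label-scan of the onset rule and the parameter formulas."""
    onset = None
    for i in range(ibt, gut - run + 1):
        if all(labels[j] == SLEEP for j in range(i, i + run)):
            onset = i
            break
    if onset is None:
        return None
    tib = gut - ibt
    sl = onset - ibt
    waso = sum(1 for j in range(onset, gut) if labels[j] == WAKE)
    tst = tib - sl - waso
    return dict(sl=sl, waso=waso, tst=tst, se=100.0 * tst / tib)


# --- in-bed detection --------------------------------------------------------

def features_frame(lying_mask, active_mask):
    n = len(lying_mask)
    return pd.DataFrame(
        {
            "minute": np.arange(n),
            "tilt_vertical_deg": np.where(lying_mask, 95.0, 5.0),
            "tilt_ml_deg": 90.0,
            "tilt_ap_deg": 90.0,
            "tpower": np.where(active_mask, -1.5, -4.0),
            "valid": True,
        }
    )


class TestDetectInBedPeriod:
    def test_single_clean_block(self):
        lying = np.zeros(700, bool)
        lying[100:500] = True
        feats = features_frame(lying, ~lying)
        cfg = DetectionConfig(rest_threshold=-3.0, min_duration_min=60)
        assert ts.detect_in_bed_period(feats, cfg) == (100, 500)

    def test_short_interruption_bridged(self):
        lying = np.zeros(700, bool)
        lying[100:500] = True
        active = ~lying
        active[300:305] = True  # 5-min active interruption
        feats = features_frame(lying, active)
        cfg = DetectionConfig(rest_threshold=-3.0, gap_tolerance_min=10,
                              min_duration_min=60)
        span = ts.detect_in_bed_period(feats, cfg)
        assert span == (100, 500)
        ind = lying & ~active
        assert span == oracle_longest_tolerant_run(ind.tolist(), 10)

    def test_all_upright_errors(self):
        feats = features_frame(np.zeros(300, bool), np.ones(300, bool))
        with pytest.raises(ts.NoInBedPeriodError):
            ts.detect_in_bed_period(feats, DetectionConfig(rest_threshold=-3.0))

    def test_block_shorter_than_minimum_errors(self):
        lying = np.zeros(300, bool)
        lying[100:160] = True
        feats = features_frame(lying, ~lying)
        with pytest.raises(ts.NoInBedPeriodError):
            ts.detect_in_bed_period(
                feats, DetectionConfig(rest_threshold=-3.0, min_duration_min=120))

    def test_otsu_threshold_on_synthetic_record(self, small_cohort):
        """Per-record Otsu rest threshold: detection lands within 2 min of
        the scheduled block on default-noise synthetic subjects."""
        for meta, truth, accel, feats in small_cohort:
            ibt, gut = ts.detect_in_bed_period(feats)
            assert abs(ibt - truth.true_params.ibt_minute) <= 2
            assert abs(gut - truth.true_params.gut_minute) <= 2

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_tolerant_run_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        ind = rng.random(n) < 0.5
        tol = int(rng.integers(0, 6))
        assert find_longest_tolerant_run(ind, tol) == \
            oracle_longest_tolerant_run(ind.tolist(), tol)


# --- sleep-parameter scoring -------------------------------------------------

class TestScoreSleep:
    def test_all_sleep_block(self):
        labels = np.ones(480, int)
        p = ts.score_sleep(labels, 0, 480)
        assert (p.sl, p.waso, p.tst, p.se) == (0, 0, 480, 100.0)

    def test_worked_example_sixty_minute_night(self):
        """From IBT: 5 wake, 10 sleep, 3 wake, 42 sleep (TIB=60)
        -> SL=5, WASO=3, TST=52, SE=86.67."""
        labels = labels_from_str(list("W" * 5 + "S" * 10 + "W" * 3 + "S" * 42))
        p = ts.score_sleep(labels, 0, 60)
        assert (p.sl, p.waso, p.tst) == (5, 3, 52)
        assert p.se == pytest.approx(86.67, abs=0.01)
        assert p.tst == p.tib - p.sl - p.waso  # accounting identity

    def test_alternating_labels_flag_onset_undefined(self):
        labels = np.array([SLEEP, WAKE] * 50)
        with pytest.raises(ts.OnsetUndefinedError):
            ts.score_sleep(labels, 0, 100)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ts.InputError):
            ts.score_sleep(np.ones(100, int), 50, 40)
        with pytest.raises(ts.InputError):
            ts.score_sleep(np.ones(100, int), 0, 200)

    def test_clock_times_follow_recording_start(self):
        from datetime import datetime

        meta = ts.SubjectMeta("C", age=30,
                              recording_start=datetime(2020, 6, 1, 11, 0))
        labels = np.ones(1000, int)
        p = ts.score_sleep(labels, 754, 1000, meta=meta)
        assert p.ibt_hhmm == "23:34"

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_label_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        labels = (rng.random(n) < 0.7).astype(int)
        ibt = int(rng.integers(0, n - 12))
        gut = int(rng.integers(ibt + 12, n + 1))
        expected = oracle_score(labels.tolist(), ibt, gut)
        if expected is None:
            with pytest.raises(ts.OnsetUndefinedError):
                ts.score_sleep(labels, ibt, gut)
        else:
            p = ts.score_sleep(labels, ibt, gut)
            assert (p.sl, p.waso, p.tst) == \
                (expected["sl"], expected["waso"], expected["tst"])
            assert p.se == pytest.approx(expected["se"])

    def test_parameter_invariants_enforced_by_type(self):
        with pytest.raises(ts.ParameterError):
            ts.SleepParameters(ibt_minute=0, gut_minute=100, tib=100,
                               sl=5, waso=5, tst=80, se=80.0)  # tst wrong


# --- inclusion screen --------------------------------------------------------

class TestInclusionCriteria:
    def meta(self, **kw):
        base = dict(subject_id="I", age=40, recording_duration=24.0,
                    noise_beat_fraction=0.01)
        base.update(kw)
        return ts.SubjectMeta(**base)

    def test_short_duration_excluded(self):
        d = apply_inclusion_criteria(meta=self.meta(recording_duration=19.0),
                                     mean_vertical_gmc=-0.5)
        assert not d.included and d.reasons == ("criterion_1_duration",)

    def test_duration_exactly_20h_excluded(self):
        d = apply_inclusion_criteria(meta=self.meta(recording_duration=20.0),
                                     mean_vertical_gmc=-0.5)
        assert "criterion_1_duration" in d.reasons

    def test_age_out_of_range_excluded(self):
        d = apply_inclusion_criteria(meta=self.meta(age=95), mean_vertical_gmc=-0.5)
        assert d.reasons == ("criterion_2_age",)
        d = apply_inclusion_criteria(meta=self.meta(age=9), mean_vertical_gmc=-0.5)
        assert d.reasons == ("criterion_2_age",)

    def test_noise_beats_excluded_at_threshold(self):
        d = apply_inclusion_criteria(meta=self.meta(noise_beat_fraction=0.10),
                                     mean_vertical_gmc=-0.5)
        assert d.reasons == ("criterion_3_noise_beats",)

    def test_vertical_gmc_strict_inequality(self):
        d = apply_inclusion_criteria(meta=self.meta(), mean_vertical_gmc=-1.0)
        assert d.reasons == ("criterion_4_vertical_gmc",)
        d = apply_inclusion_criteria(meta=self.meta(), mean_vertical_gmc=-0.999)
        assert d.included

    def test_multiple_failures_all_reported(self):
        d = apply_inclusion_criteria(
            meta=self.meta(age=95, recording_duration=10.0), mean_vertical_gmc=-1.0)
        assert set(d.reasons) == {"criterion_1_duration", "criterion_2_age",
                                  "criterion_4_vertical_gmc"}

    def test_missing_gmc_reported(self):
        d = apply_inclusion_criteria(meta=self.meta(), mean_vertical_gmc=None)
        assert d.reasons == ("missing:vertical_gmc",)
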