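"""Shared fixtures: small synthetic subjects and cohort tables.

Everything is generated programmatically at test time; session scope keeps
the expensive full-resolution subjects to a handful of synthesis calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import trunksleep as ts
from trunksleep import glm


@pytest.fixture(scope="session")
def default_cohort_config() -> ts.CohortConfig:
    return ts.CohortConfig(n_subjects=4, seed=123)


@pytest.fixture(scope="session")
def small_cohort(default_cohort_config):
    """Four fully synthesized subjects (meta, truth, accel, features)."""
    out = []
    for subj in ts.generate_cohort(default_cohort_config):
        feats = ts.extract_minute_features(ts.split_components(subj.accel))
        out.append((subj.meta, subj.truth, subj.accel, feats))
    return out


def truth_cohort_table(config: ts.CohortConfig) -> pd.DataFrame:
    """Cohort table built from ground-truth parameters (no signal synthesis)."""
    rows = []
    for subj in ts.generate_cohort(config, include_acceleration=False):
        tp = subj.truth.true_params
        rows.append(
            {
                "subject_id": subj.meta.subject_id,
                "age": subj.meta.age,
                "gender": subj.meta.gender,
                "month": subj.meta.recording_month,
                "ibt_mfm": tp.minutes_from_midnight(tp.ibt_minute),
                "gut_mfm": tp.minutes_from_midnight(tp.gut_minute),
                "tib_min": tp.tib,
                "sl_min": tp.sl,
                "waso_min": tp.waso,
                "tst_min": tp.tst,
                "se_pct": tp.se,
            }
        )
    return glm.build_cohort_table(pd.DataFrame(rows))


def null_cohort_config(n_subjects: int, seed: int) -> ts.CohortConfig:
    """A cohort with every configured age/gender effect switched off."""
    return ts.CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        ibt_advance_per_decade=0.0,
        gut_advance_per_decade=0.0,
        waso_slope_per_decade=0.0,
        gender_tst_gap=0.0,
        tib_curve={d: 0.0 for d in range(1, 9)},
    )


@pytest.fixture(scope="session")
def effect_cohort_table() -> pd.DataFrame:
    """A mid-sized cohort with the default (non-null) effects."""
    return truth_cohort_table(ts.CohortConfig(n_subjects=800, seed=77))
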