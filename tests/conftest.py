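"""Shared fixtures: one small synthetic cohort, generated once per session
and carried through the pipeline stages."""

import numpy as np
import pandas as pd
import pytest

from somnoscope import hmm, preprocess, simulate, sleep


@pytest.fixture(scope="session")
def small_config():
    return simulate.GeneratorConfig(n_subjects=20, seed=7)


@pytest.fixture(scope="session")
def cohort(small_config):
    """(minutes, demographics, truth) for a 20-subject cohort."""
    return simulate.generate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_series(cohort):
    minutes, _, _ = cohort
    clean, day_qc, subject_qc = preprocess.preprocess(minutes)
    return clean, day_qc, subject_qc


@pytest.fixture(scope="session")
def labelled(clean_series):
    clean, _, _ = clean_series
    labels, models = hmm.score_cohort(clean)
    return labels, models


@pytest.fixture(scope="session")
def nights(labelled):
    labels, _ = labelled
    return sleep.score_nights(labels)


def make_minutes(values, wear=None, flags=None, subject_id=1, day=1, dow=2,
                 start_minute=0):
    """Hand-build a minute-table fragment for boundary tests."""
    n = len(values)
    wear = wear if wear is not None else ["wake-wear"] * n
    flags = flags if flags is not None else [0] * n
    mod = (start_minute + np.arange(n))
    return pd.DataFrame({
        "subject_id": subject_id,
        "day_index": day + mod // 1440,
        "minute_of_day": mod % 1440,
        "calendar_dow": ((dow - 1 + mod // 1440) % 7) + 1,
        "mims_triaxial": np.asarray(values, float),
        "wear_pred": wear,
        "quality_flag_count": flags,
    })
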