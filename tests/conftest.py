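"""Shared fixtures: expensive cohort simulations are session-scoped."""

import numpy as np
import pandas as pd
import pytest

from fearext.scoring import score_session
from fearext.synthetic import default_effect_model, simulate_cohort
from fearext.task_design import DesignConfig

COHORT_SEED = 42


@pytest.fixture(scope="session")
def design():
    return DesignConfig()


@pytest.fixture(scope="session")
def effect_model():
    return default_effect_model()


@pytest.fixture(scope="session")
def cohort38():
    """Default 38-subject cohort at the published study conditions."""
    return simulate_cohort(n_subjects=38, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def scored38(cohort38):
    """All 38 sessions scored with default settings."""
    frames = [
        score_session(cohort38.recordings[sid],
                      cohort38.events[cohort38.events.subject_id == sid])
        for sid in sorted(cohort38.recordings)
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def truth38(cohort38):
    return cohort38.truth.sort_values(
        ["subject_id", "phase", "trial_index"]).reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
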