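import numpy as np
import pandas as pd
import pytest

from icpredict.cohort import CohortConfig, simulate_cohort
from icpredict.preprocessing import load_dictionary

#: A wave record with every instrument at its best value.
COMPLETE_RECORD = {
    "subject_id": "S1",
    "wave_index": 1,
    "age": 70.0,
    "sex": 1,
    "marital_status": "married",
    "education": 4,
    "bmi": 26.0,
    "hearing_left": 5,
    "hearing_right": 5,
    "vision_far": 5,
    "vision_near": 5,
    "sppb_balance": 4,
    "sppb_gait": 4,
    "sppb_chair": 4,
    "sppb_gait_time": 4.0,
    "sppb_chair_time": 9.0,
    "moca_total": 30,
    "phq9_total": 0,
    "sf12_q1": 1, "sf12_q2": 1, "sf12_q3": 1, "sf12_q4": 1, "sf12_q5": 1,
    "sf12_q6": 1, "sf12_q8": 1, "sf12_q10": 1, "sf12_q11": 1,
    "iadl_q1": 1, "iadl_q2": 1, "iadl_q3": 1, "iadl_q4": 1, "iadl_q5": 1,
    "iadl_q7": 1, "iadl_q8": 1,
    "ucla_q1": 1, "ucla_q2": 1, "ucla_q4": 1, "ucla_q11": 1, "ucla_q14": 1,
    "lubben_q6": 5, "lubben_q12": 5,
    "eq5d_q1": 1, "eq5d_q2": 1, "eq5d_q4": 1, "eq5d_q5": 1,
    "grip_kg": 30.0,
}


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary()


@pytest.fixture()
def complete_record():
    return dict(COMPLETE_RECORD)


def make_panel(n_subjects, waves, base=None):
    """Complete wave table: n_subjects x the given wave indices."""
    base = base or COMPLETE_RECORD
    rows = []
    for i in range(n_subjects):
        for t in waves:
            rec = dict(base)
            rec["subject_id"] = f"S{i}"
            rec["wave_index"] = t
            rec["age"] = 70.0 + 2.0 * (t - 1)
            rows.append(rec)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small fully observed synthetic cohort (no missingness, no dropout)."""
    cfg = CohortConfig(n_subjects=80, n_waves=4, seed=11).without_missingness()
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def messy_cohort():
    """Cohort with default missingness and dropout."""
    return simulate_cohort(CohortConfig(n_subjects=120, n_waves=4, seed=23))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
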