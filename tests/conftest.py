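import warnings

import numpy as np
import pandas as pd
import pytest

from sensormiss import SensorSchedule, SimConfig, generate_cohort, simulate_panel
from sensormiss.simulate import GPS_TRUE_PARAMS

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def gps_schedule():
    """1 min on / 9 min off: the canonical 10%-coverage GPS design."""
    return SensorSchedule("gps", 60, 540)


@pytest.fixture(scope="session")
def tiny_config(gps_schedule):
    return SimConfig(
        n_studies=2,
        participants_per_study=5,
        days_per_participant=12,
        schedule=gps_schedule,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    cohort = generate_cohort(tiny_config)
    panel, truth = simulate_panel(cohort, GPS_TRUE_PARAMS, tiny_config)
    return panel, truth


@pytest.fixture(scope="session")
def small_covariates():
    """Hand-written 4-participant covariate table with one missing value."""
    return pd.DataFrame(
        {
            "participant_id": ["p1", "p2", "p3", "p4"],
            "study_id": ["s1", "s1", "s2", "s2"],
            "os": ["Android", "iOS", "Android", "Android"],
            "gender": ["Female", "Male", "Female", np.nan],
            "education": ["High school", "Bachelors", "High school", "Graduate degree"],
            "race_ethnicity": [
                "non-Hispanic White",
                "Asian",
                "non-Hispanic Black",
                "non-Hispanic White",
            ],
            "age_years": [25.0, 31.5, 19.0, 44.0],
        }
    )
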