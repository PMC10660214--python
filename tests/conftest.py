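import numpy as np
import pandas as pd
import pytest

from lookback import SimulationConfig, simulate_claims


def make_claims(rows):
    """Build a claims frame from (patient_id, sex, birth, type, date, codes) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sex", "birth_date", "claim_type", "service_date",
            "diagnosis_codes",
        ],
    )
    df["service_date"] = pd.to_datetime(df["service_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


@pytest.fixture
def tiny_claims():
    """Three patients: an inpatient case, a 3-outpatient case, a non-case."""
    return make_claims(
        [
            ("A", "female", "1960-05-01", "inpatient", "2020-03-01", "E11.9"),
            ("B", "male", "1955-01-01", "outpatient", "2020-02-01", "E14"),
            ("B", "male", "1955-01-01", "outpatient", "2020-06-15", "E11.2"),
            ("B", "male", "1955-01-01", "outpatient", "2020-11-30", "E10.9"),
            ("C", "female", "1980-07-07", "outpatient", "2020-04-01", "E11.9"),
            ("C", "female", "1980-07-07", "outpatient", "2020-05-01", "E11.9"),
            ("C", "female", "1980-07-07", "outpatient", "2020-06-01", "I10"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated cohort shared across tests (seeded)."""
    cfg = SimulationConfig(
        n_patients=600,
        seed=20160101,
        missing_sex_probability=0.0,
        missing_diagnosis_probability=0.0,
    )
    claims, truth = simulate_claims(cfg)
    return cfg, claims, truth
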