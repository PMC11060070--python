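import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import nestedcc as ncc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_tables():
    """A medium synthetic EHR under the default (true rate ratio 2) config."""
    cfg = ncc.SimulationConfig(n_patients=5000, seed=1)
    return cfg, ncc.generate_ehr(cfg)


@pytest.fixture(scope="session")
def default_cohort(default_tables):
    _, t = default_tables
    cohort, tally = ncc.build_cohort(
        t["patients"], t["prescriptions"], t["clinical_events"], t["deaths"]
    )
    return cohort, tally


@pytest.fixture(scope="session")
def null_tables():
    """Tables under the sharp null: no exposure effect, no confounding."""
    cfg = ncc.SimulationConfig(
        n_patients=5000, seed=2, beta_ad=0.0, severity_link=0.0
    )
    return cfg, ncc.generate_ehr(cfg)


def _patient(pid, gender="female", yob=1950, practice="G000",
             reg_start="2000-01-01", reg_end="2019-12-31", ethnicity="white",
             severity=0.0):
    return dict(
        patient_id=pid, gender=gender, year_of_birth=yob, practice_id=practice,
        registration_start=np.datetime64(reg_start, "D"),
        registration_end=np.datetime64(reg_end, "D"),
        ethnicity=ethnicity, latent_severity=severity,
    )


def _rx(pid, date, drug_class="oral_antidiabetic", agent="metformin", duration=28):
    return dict(patient_id=pid, date=np.datetime64(date, "D"),
                drug_class=drug_class, agent=agent, duration_days=duration)


def _event(pid, date, category, value=""):
    return dict(patient_id=pid, date=np.datetime64(date, "D"),
                code_category=category, value=value)


def _death(pid, date, cause="cardiovascular"):
    return dict(patient_id=pid, death_date=np.datetime64(date, "D"),
                cause_category=cause)


def make_tables(patients, prescriptions=(), events=(), deaths=()):
    """Assemble micro EHR tables from row dicts for rule-level tests."""
    from nestedcc.tables import (
        DEATH_COLUMNS,
        EVENT_COLUMNS,
        PATIENT_COLUMNS,
        PRESCRIPTION_COLUMNS,
    )

    return {
        "patients": pd.DataFrame(list(patients), columns=PATIENT_COLUMNS),
        "prescriptions": pd.DataFrame(list(prescriptions), columns=PRESCRIPTION_COLUMNS),
        "clinical_events": pd.DataFrame(list(events), columns=EVENT_COLUMNS),
        "deaths": pd.DataFrame(list(deaths), columns=DEATH_COLUMNS),
    }


@pytest.fixture
def micro():
    """Row-builder helpers for hand-constructed tables."""
    return dict(patient=_patient, rx=_rx, event=_event, death=_death,
                tables=make_tables)


def qualifying_patient_rows(pid="P1", entry="2005-01-01", **kw):
    """Rows that make one patient pass every cohort inclusion rule."""
    rows = {
        "patients": [_patient(pid, **kw)],
        "prescriptions": [_rx(pid, entry)],
        "events": [
            _event(pid, "2004-06-01", "glucose_test", "15.000"),
            _event(pid, "2004-08-01", "glucose_test", "14.000"),
            _event(pid, np.datetime64(entry, "D") + 30, "depression"),
        ],
        "deaths": [],
    }
    return rows
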