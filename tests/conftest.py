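import datetime as dt

import pandas as pd
import pytest

from riskprofile import reference_fixture
from riskprofile.synthetic_data import SimulationParams, simulate_dataset

CUTOFF = dt.date(2020, 11, 5)


@pytest.fixture(scope="session")
def kb():
    return reference_fixture()


@pytest.fixture(scope="session")
def small_dataset(kb):
    """One modest simulated region reused across tests (deterministic)."""
    params = SimulationParams(n_patients=600, seed=11)
    patients, events, truth = simulate_dataset(params, kb)
    return params, patients, events, truth


def make_events(rows):
    """Events frame from (pid, type, atc, form, date[, order_start, order_end]) tuples."""
    from riskprofile.cohort_builder import EVENT_COLUMNS

    full = []
    for r in rows:
        r = list(r)
        while len(r) < 7:
            r.append(None)
        pid, etype, atc, form, date, ostart, oend = r
        full.append((pid, etype, atc, form, pd.Timestamp(date),
                     pd.Timestamp(ostart) if ostart else pd.NaT,
                     pd.Timestamp(oend) if oend else pd.NaT,
                     "physician", False))
    df = pd.DataFrame(full, columns=EVENT_COLUMNS)
    for col in ("event_date", "order_start", "order_end"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_patients(rows):
    """Patients frame from (pid, gender, birth[, death, resident]) tuples."""
    from riskprofile.cohort_builder import PATIENT_COLUMNS

    full = []
    for r in rows:
        r = list(r)
        while len(r) < 5:
            r.append(None)
        pid, gender, birth, death, resident = r
        full.append((pid, gender, pd.Timestamp(birth),
                     pd.Timestamp(death) if death else pd.NaT,
                     True if resident is None else resident))
    df = pd.DataFrame(full, columns=PATIENT_COLUMNS)
    for col in ("birth_date", "death_date"):
        df[col] = pd.to_datetime(df[col])
    return df
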