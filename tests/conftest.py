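import pandas as pd
import pytest

import icuward as iw
import icuward.features as F


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated dataset shared across tests (40 cases, 200 controls)."""
    cfg = iw.GeneratorConfig(n_case_encounters=40, n_control_encounters=200,
                             seed=123)
    encounters, events, truth = iw.generate(cfg)
    return cfg, encounters, events, truth


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    cfg, encounters, events, truth = small_dataset
    cohort = iw.build_cohort(encounters, events, ratio=5.0, seed=123)
    return cohort


@pytest.fixture(scope="session")
def small_index(small_dataset):
    _, _, events, _ = small_dataset
    return F.EventIndex(events)


def make_adt(rows):
    """ADT frame from (encounter_id, unit_type, start_h, end_h) tuples with
    hours counted from a fixed origin."""
    origin = pd.Timestamp("2012-01-01")
    recs = [("P" + eid[1:], eid, unit,
             origin + pd.Timedelta(hours=s), origin + pd.Timedelta(hours=e))
            for eid, unit, s, e in rows]
    return pd.DataFrame(recs, columns=["patient_id", "encounter_id",
                                       "unit_type", "start", "end"])


def make_events(rows):
    """Event frame from (encounter_id, t_hours, category, attribute, value)
    tuples, hours from the same fixed origin as :func:`make_adt`."""
    origin = pd.Timestamp("2012-01-01")
    recs = [("P" + eid[1:], eid, origin + pd.Timedelta(hours=t), cat, attr,
             value, "") for eid, t, cat, attr, value in rows]
    df = pd.DataFrame(recs, columns=["patient_id", "encounter_id",
                                     "timestamp", "category", "attribute",
                                     "value", "unit"])
    df["value"] = df["value"].astype(object)
    return df


ORIGIN = pd.Timestamp("2012-01-01")


def hours(h):
    return ORIGIN + pd.Timedelta(hours=h)
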