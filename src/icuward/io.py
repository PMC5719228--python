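"""Reading and writing event streams, ADT tables, and cohort files.

Clinical observations travel as an *event stream*: one record per timestamped
observation (a vital sign, a lab result, an acuity score, a nursing-assessment
attribute-value pair, a medication administration, or a respiratory-support
event), serialized as JSON Lines.  Unit stays (admission-discharge-transfer
segments) and per-encounter demographics are plain CSV.  All on-disk formats
are text and round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EVENT_CATEGORIES = ("vital", "lab", "acuity", "assessment", "med", "resp_support")
UNIT_TYPES = ("floor", "ED", "OR", "PACU", "ICU", "NICU")

EVENT_COLUMNS = ["patient_id", "encounter_id", "timestamp", "category",
                 "attribute", "value", "unit"]
ADT_COLUMNS = ["patient_id", "encounter_id", "unit_type", "start", "end"]
INFO_COLUMNS = ["patient_id", "encounter_id", "admit_time", "age_years",
                "diagnosis_group"]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


class EventStreamError(ValueError):
    """A malformed record in an event-stream file (message names the line)."""


@dataclass
class Encounters:
    """Unit-stay (ADT) segments plus per-encounter demographics.

    ``adt`` has one row per unit stay: patient_id, encounter_id, unit_type
    (floor/ED/OR/PACU/ICU/NICU), start, end.  ``info`` has one row per
    encounter: patient_id, encounter_id, admit_time, age_years,
    diagnosis_group.
    """

    adt: pd.DataFrame
    info: pd.DataFrame

    def equals(self, other: "Encounters") -> bool:
        return self.adt.equals(other.adt) and self.info.equals(other.info)


def _format_ts(ts: pd.Timestamp) -> str:
    return ts.strftime(_TS_FORMAT)


def write_events_jsonl(events: pd.DataFrame, path) -> None:
    """Write an event stream as JSON Lines (one observation per line)."""
    path = Path(path)
    with path.open("w") as fh:
        for row in events.itertuples(index=False):
            rec = {
                "patient_id": row.patient_id,
                "encounter_id": row.encounter_id,
                "timestamp": _format_ts(row.timestamp),
                "category": row.category,
                "attribute": row.attribute,
                "value": row.value,
                "unit": row.unit,
            }
            fh.write(json.dumps(rec) + "\n")


def read_events_jsonl(path) -> pd.DataFrame:
    """Read a JSON Lines event stream; malformed records name their line."""
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EventStreamError(f"{path}: line {lineno}: invalid JSON ({exc})")
            for key in ("patient_id", "encounter_id", "timestamp", "category",
                        "attribute", "value"):
                if rec.get(key) is None:
                    raise EventStreamError(
                        f"{path}: line {lineno}: missing field '{key}'")
            try:
                ts = pd.Timestamp(rec["timestamp"])
            except (ValueError, TypeError):
                raise EventStreamError(
                    f"{path}: line {lineno}: unparseable timestamp "
                    f"{rec['timestamp']!r}")
            if rec["category"] not in EVENT_CATEGORIES:
                raise EventStreamError(
                    f"{path}: line {lineno}: unknown category {rec['category']!r}")
            value = rec["value"]
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                value = float(value)
            records.append((rec["patient_id"], rec["encounter_id"], ts,
                            rec["category"], rec["attribute"], value,
                            rec.get("unit", "")))
    events = pd.DataFrame(records, columns=EVENT_COLUMNS)
    if len(events) == 0:
        events = _empty_events()
    else:
        events["timestamp"] = pd.to_datetime(events["timestamp"])
        for col in ("value", "unit"):
            events[col] = events[col].astype(object)
    return events


def _empty_events() -> pd.DataFrame:
    events = pd.DataFrame({c: pd.Series(dtype=object) for c in EVENT_COLUMNS})
    events["timestamp"] = pd.Series(dtype="datetime64[ns]")
    return events[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, encounters: Encounters, path) -> None:
    """Write a full dataset (events.jsonl, adt.csv, encounters.csv) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_events_jsonl(events, path / "events.jsonl")
    adt = encounters.adt.copy()
    for col in ("start", "end"):
        adt[col] = adt[col].dt.strftime(_TS_FORMAT)
    adt.to_csv(path / "adt.csv", index=False)
    info = encounters.info.copy()
    info["admit_time"] = info["admit_time"].dt.strftime(_TS_FORMAT)
    info.to_csv(path / "encounters.csv", index=False)


def read_events(path) -> tuple[Encounters, pd.DataFrame]:
    """Read a dataset directory written by :func:`write_events`."""
    path = Path(path)
    events = read_events_jsonl(path / "events.jsonl")
    adt = pd.read_csv(path / "adt.csv", dtype={"patient_id": str, "encounter_id": str})
    if len(adt):
        for col in ("start", "end"):
            adt[col] = pd.to_datetime(adt[col], format=_TS_FORMAT)
        bad = ~adt["unit_type"].isin(UNIT_TYPES)
        if bad.any():
            raise EventStreamError(
                f"{path / 'adt.csv'}: unknown unit types "
                f"{sorted(adt.loc[bad, 'unit_type'].unique())}")
    else:
        adt = pd.DataFrame({c: pd.Series(dtype=object) for c in ADT_COLUMNS})
        for col in ("start", "end"):
            adt[col] = pd.Series(dtype="datetime64[ns]")
    info = pd.read_csv(path / "encounters.csv",
                       dtype={"patient_id": str, "encounter_id": str})
    if len(info):
        info["admit_time"] = pd.to_datetime(info["admit_time"], format=_TS_FORMAT)
        info["age_years"] = info["age_years"].astype(float)
    else:
        info = pd.DataFrame({c: pd.Series(dtype=object) for c in INFO_COLUMNS})
        info["admit_time"] = pd.Series(dtype="datetime64[ns]")
        info["age_years"] = pd.Series(dtype=float)
    return Encounters(adt=adt[ADT_COLUMNS], info=info[INFO_COLUMNS]), events


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["event_time"] = out["event_time"].dt.strftime(_TS_FORMAT)
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, dtype={"encounter_id": str})
    cohort["event_time"] = pd.to_datetime(cohort["event_time"], format=_TS_FORMAT)
    for col in ("c1", "c2", "c3", "c4", "c5", "cde"):
        cohort[col] = cohort[col].astype(bool)
    return cohort
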