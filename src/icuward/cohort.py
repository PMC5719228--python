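"""Cohort construction: candidate transfers, unplanned criteria, CDE, controls.

Candidate cases are floor-to-ICU transfers found in ADT data (transfers
originating from the ED, OR, PACU, or ICU are excluded, as are transfers into
the NICU).  A candidate becomes a *case* when at least one of five heuristic
urgency criteria fires in a window around the transfer: initiation of
noninvasive (CPAP/BiPAP) or invasive ventilation; vasopressor administration;
an NS/LR fluid bolus above a volume-per-weight threshold; an emergent
procedure or resuscitation event; or an ICU-only medication on the MAR.
Cases with positive-pressure ventilation, vasopressors, fluid resuscitation,
or emergent procedures within [transfer-2h, transfer+12h] are additionally
flagged as critical deterioration events (CDE).

Controls are sampled from encounters that were never in an ICU and spent at
least 24 hours on an inpatient floor, stratified over age-bin x diagnosis
cells proportional to the case distribution.  Both cases and controls must
have at least 8 hours of floor time before their event.  The unit of
analysis is the transfer, not the patient: an encounter with several
qualifying transfers contributes several case records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Encounters
from .synth import (AGE_BIN_LABELS, EMERGENT_PROCEDURES, FLUID_BOLUSES,
                    ICU_ONLY_MEDS, RESP_SUPPORT_ATTRS, VASOPRESSORS, age_bin)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["encounter_id", "label", "event_time", "c1", "c2", "c3",
                  "c4", "c5", "cde", "floor_hours", "age_years",
                  "diagnosis_group"]

#: Five configurable predicates identifying an "unplanned" transfer.  Each
#: names the event categories/attributes it watches and the closed window
#: (hours relative to the transfer) it searches.  The bolus predicate also
#: requires a numeric value (mL/kg) at or above ``min_value``.
DEFAULT_CRITERIA: dict[str, dict] = {
    "respiratory_support": {
        "categories": ("resp_support",),
        "attributes": RESP_SUPPORT_ATTRS,
        "window_hours": (-2.0, 12.0),
    },
    "vasopressor": {
        "categories": ("med",),
        "attributes": VASOPRESSORS,
        "window_hours": (-2.0, 12.0),
    },
    "fluid_bolus": {
        "categories": ("med",),
        "attributes": FLUID_BOLUSES,
        "window_hours": (-2.0, 12.0),
        "min_value": 20.0,  # mL/kg
    },
    "emergent_procedure": {
        "categories": ("med",),
        "attributes": EMERGENT_PROCEDURES,
        "window_hours": (-2.0, 12.0),
    },
    "icu_only_medication": {
        "categories": ("med",),
        "attributes": ICU_ONLY_MEDS,
        "window_hours": (-2.0, 12.0),
    },
}

CRITERIA_ORDER = tuple(DEFAULT_CRITERIA)

CDE_WINDOW_HOURS = (-2.0, 12.0)
CDE_ATTRIBUTES = tuple(RESP_SUPPORT_ATTRS) + tuple(VASOPRESSORS) + \
    tuple(FLUID_BOLUSES) + tuple(EMERGENT_PROCEDURES)


@dataclass(frozen=True)
class CandidateTransfer:
    encounter_id: str
    transfer_time: pd.Timestamp


def _validate_segments(segs: pd.DataFrame) -> pd.DataFrame:
    segs = segs.sort_values("start", kind="stable")
    if (segs["start"] >= segs["end"]).any():
        raise ValueError("ADT segment with start >= end")
    if (segs["start"].iloc[1:].to_numpy() <
            segs["end"].iloc[:-1].to_numpy()).any():
        raise ValueError(
            f"overlapping ADT segments for encounter "
            f"{segs['encounter_id'].iloc[0]!r}")
    return segs


def extract_candidate_transfers(adt: pd.DataFrame) -> list[CandidateTransfer]:
    """Every floor->ICU adjacency in the ADT data, one candidate per transfer.

    Transfers originating from ED/OR/PACU/ICU are never candidates (the
    origin segment must be a floor stay) and transfers into the NICU are
    excluded (the destination must be the ICU proper).
    """
    candidates = []
    for eid, segs in adt.groupby("encounter_id", sort=True):
        segs = _validate_segments(segs)
        units = segs["unit_type"].to_numpy()
        starts = segs["start"].to_numpy()
        for i in range(len(segs) - 1):
            if units[i] == "floor" and units[i + 1] == "ICU":
                candidates.append(CandidateTransfer(
                    encounter_id=eid,
                    transfer_time=pd.Timestamp(starts[i + 1])))
    return candidates


def _events_in_window(events: pd.DataFrame, center: pd.Timestamp,
                      window_hours: tuple[float, float]) -> pd.DataFrame:
    lo = center + pd.Timedelta(hours=window_hours[0])
    hi = center + pd.Timedelta(hours=window_hours[1])
    # closed interval on both sides
    mask = (events["timestamp"] >= lo) & (events["timestamp"] <= hi)
    return events[mask]


def apply_unplanned_criteria(candidate: CandidateTransfer,
                             events: pd.DataFrame,
                             criteria: dict | None = None) -> dict[str, bool]:
    """Evaluate the five unplanned-transfer predicates for one candidate.

    ``events`` may be the full stream; only the candidate's encounter is
    consulted.  Returns an ordered name->bool mapping; a candidate with at
    least one true flag is a case.
    """
    criteria = DEFAULT_CRITERIA if criteria is None else criteria
    enc_events = events[events["encounter_id"] == candidate.encounter_id]
    flags: dict[str, bool] = {}
    for name, spec in criteria.items():
        unknown = set(spec) - {"categories", "attributes", "window_hours",
                               "min_value"}
        if unknown:
            raise ValueError(f"unknown keys {sorted(unknown)} in criterion "
                             f"{name!r}")
        windowed = _events_in_window(enc_events, candidate.transfer_time,
                                     tuple(spec["window_hours"]))
        hit = windowed[windowed["category"].isin(spec["categories"]) &
                       windowed["attribute"].isin(spec["attributes"])]
        if "min_value" in spec and len(hit):
            vals = pd.to_numeric(hit["value"], errors="coerce")
            hit = hit[vals >= float(spec["min_value"])]
        flags[name] = bool(len(hit))
    return flags


def identify_cde(encounter_id: str, transfer_time: pd.Timestamp,
                 events: pd.DataFrame) -> bool:
    """True iff a ventilation/vasopressor/fluid-resuscitation/emergent-procedure
    event lies in the closed window [transfer-2h, transfer+12h]."""
    enc_events = events[events["encounter_id"] == encounter_id]
    windowed = _events_in_window(enc_events, transfer_time, CDE_WINDOW_HOURS)
    return bool(windowed["attribute"].isin(CDE_ATTRIBUTES).any())


def floor_hours_before(adt: pd.DataFrame, encounter_id: str,
                       event_time: pd.Timestamp) -> float:
    """Total hours spent in floor segments before ``event_time`` (summed
    across segments, each truncated at the event)."""
    segs = adt[(adt["encounter_id"] == encounter_id) &
               (adt["unit_type"] == "floor")]
    total = 0.0
    for row in segs.itertuples(index=False):
        end = min(row.end, event_time)
        if end > row.start:
            total += (end - row.start).total_seconds() / 3600.0
    return total


def control_pool(encounters: Encounters) -> pd.DataFrame:
    """Encounters eligible as controls: no ICU segment, >= 24 h floor time.

    Returns one row per eligible encounter with its floor-departure time
    (end of the last floor segment) and floor hours.
    """
    adt = encounters.adt
    icu_encounters = set(adt.loc[adt["unit_type"] == "ICU", "encounter_id"])
    rows = []
    for eid, segs in adt.groupby("encounter_id", sort=True):
        if eid in icu_encounters:
            continue
        floor = segs[segs["unit_type"] == "floor"]
        if len(floor) == 0:
            continue
        hours = ((floor["end"] - floor["start"]).dt.total_seconds() / 3600.0).sum()
        if hours < 24.0:
            continue
        rows.append((eid, floor["end"].max(), hours))
    return pd.DataFrame(rows, columns=["encounter_id", "event_time",
                                       "floor_hours"])


def select_controls(encounters: Encounters, cases: pd.DataFrame,
                    ratio: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Stratified control sample matched to the case age/diagnosis mix.

    Samples roughly ``ratio`` controls per case from the eligible pool, with
    per-stratum (age bin x diagnosis group) counts proportional to the case
    distribution.  An empty stratum falls back to the nearest age bin within
    the same diagnosis group, then to the whole pool (logged).  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pool = control_pool(encounters)
    info = encounters.info.set_index("encounter_id")
    pool = pool.join(info[["age_years", "diagnosis_group"]],
                     on="encounter_id")
    pool["age_bin"] = pool["age_years"].map(age_bin)

    cases = cases.copy()
    cases["age_bin"] = cases["age_years"].map(age_bin)
    strata = cases.groupby(["age_bin", "diagnosis_group"]).size()
    n_target = int(round(ratio * len(cases)))

    chosen: list[str] = []
    taken: set[str] = set()
    for (bin_label, dx), n_cases_stratum in sorted(strata.items()):
        want = int(round(ratio * n_cases_stratum))
        sub = pool[(pool["age_bin"] == bin_label) &
                   (pool["diagnosis_group"] == dx) &
                   ~pool["encounter_id"].isin(taken)]
        if len(sub) < want:
            # nearest-age-bin fallback within the diagnosis group
            order = sorted(AGE_BIN_LABELS,
                           key=lambda b: abs(AGE_BIN_LABELS.index(b) -
                                             AGE_BIN_LABELS.index(bin_label)))
            for alt in order[1:]:
                if len(sub) >= want:
                    break
                extra = pool[(pool["age_bin"] == alt) &
                             (pool["diagnosis_group"] == dx) &
                             ~pool["encounter_id"].isin(taken) &
                             ~pool["encounter_id"].isin(sub["encounter_id"])]
                sub = pd.concat([sub, extra])
            if len(sub) < want:
                logger.info("stratum (%s, %s) short by %d controls; "
                            "falling back to full pool", bin_label, dx,
                            want - len(sub))
                extra = pool[~pool["encounter_id"].isin(taken) &
                             ~pool["encounter_id"].isin(sub["encounter_id"])]
                sub = pd.concat([sub, extra])
        take = min(want, len(sub))
        if take:
            idx = rng.choice(len(sub), size=take, replace=False)
            picked = sub["encounter_id"].to_numpy()[np.sort(idx)]
            chosen.extend(picked)
            taken.update(picked)

    # top up / trim to the overall target deterministically
    if len(chosen) < n_target:
        remaining = pool[~pool["encounter_id"].isin(taken)]
        extra = min(n_target - len(chosen), len(remaining))
        if extra:
            idx = rng.choice(len(remaining), size=extra, replace=False)
            chosen.extend(remaining["encounter_id"].to_numpy()[np.sort(idx)])
    elif len(chosen) > n_target:
        chosen = chosen[:n_target]

    selected = pool[pool["encounter_id"].isin(chosen)].copy()
    selected["label"] = "control"
    for c in ("c1", "c2", "c3", "c4", "c5", "cde"):
        selected[c] = False
    return selected[COHORT_COLUMNS].reset_index(drop=True)


def apply_time_filters(records: pd.DataFrame) -> pd.DataFrame:
    """Drop any case or control with under 8 hours of floor time before its
    event (inclusive boundary: exactly 8.0 h is retained), and any control
    with under 24 hours."""
    keep = records["floor_hours"] >= 8.0
    keep &= (records["label"] == "case") | (records["floor_hours"] >= 24.0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("time filters removed %d records", dropped)
    return records[keep].reset_index(drop=True)


def build_cohort(encounters: Encounters, events: pd.DataFrame,
                 ratio: float = 5.0, seed: int = 0,
                 criteria: dict | None = None) -> pd.DataFrame:
    """Full cohort construction: candidates -> criteria -> CDE -> controls.

    Returns one row per case transfer and per selected control encounter with
    columns encounter_id, label, event_time, c1..c5, cde, floor_hours,
    age_years, diagnosis_group.
    """
    info = encounters.info.set_index("encounter_id")
    # criteria and CDE only consult intervention events; pre-filter once
    interventions = events[events["category"].isin(("med", "resp_support"))]
    rows = []
    for cand in extract_candidate_transfers(encounters.adt):
        flags = apply_unplanned_criteria(cand, interventions, criteria)
        if not any(flags.values()):
            continue
        cde = identify_cde(cand.encounter_id, cand.transfer_time, interventions)
        hours = floor_hours_before(encounters.adt, cand.encounter_id,
                                   cand.transfer_time)
        meta = info.loc[cand.encounter_id]
        rows.append((cand.encounter_id, "case", cand.transfer_time,
                     *[flags[name] for name in CRITERIA_ORDER], cde, hours,
                     float(meta["age_years"]), meta["diagnosis_group"]))
    cases = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    cases = apply_time_filters(cases) if len(cases) else cases
    if len(cases) == 0:
        return cases
    controls = select_controls(encounters, cases, ratio=ratio, seed=seed)
    cohort = pd.concat([cases, controls], ignore_index=True)
    return apply_time_filters(cohort)
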