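"""Seeded synthetic EHR encounters and event streams with known ground truth.

Real unplanned-transfer cohorts live in private hospital EHR extracts.  This
module emulates the structure of such data so every downstream stage —
cohort heuristics, feature operators, classifiers, horizon experiments — is
testable end to end: multi-unit encounters (ED/floor/ICU), irregularly
sampled numeric vitals, sparse labs with Low/Normal/High ranges, integer
acuity scores, categorical nursing-assessment attribute-value pairs, and
intervention events (positive-pressure ventilation, vasopressors, fluid
boluses) clustered around ICU transfer for cases.

The deterioration signal is a latent severity ramp: zero until a configured
onset time before the case's ICU transfer, rising linearly to ``effect_size``
(in within-type standard-deviation units) at the transfer itself.  Vitals
drift toward their abnormal direction, acuity scores rise, assessment values
shift toward abnormal vocabulary entries.  Controls carry no signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Encounters, ADT_COLUMNS, EVENT_COLUMNS, INFO_COLUMNS

# ---------------------------------------------------------------------------
# Catalogs: the synthetic clinical-element vocabulary.

# vital -> (baseline, sd, abnormal direction, unit)
VITALS = {
    "heart_rate": (120.0, 15.0, +1, "bpm"),
    "respiratory_rate": (28.0, 6.0, +1, "breaths/min"),
    "temperature": (37.0, 0.5, +1, "degC"),
    "systolic_bp": (95.0, 10.0, -1, "mmHg"),
    "oxygen_saturation": (98.0, 1.5, -1, "%"),
}

# lab -> (low, high, mean, sd, abnormal direction, unit)
LABS = {
    "sodium": (135.0, 145.0, 140.0, 2.5, -1, "mmol/L"),
    "potassium": (3.5, 5.0, 4.2, 0.4, +1, "mmol/L"),
    "glucose": (70.0, 140.0, 100.0, 20.0, +1, "mg/dL"),
    "creatinine": (0.3, 1.0, 0.6, 0.15, +1, "mg/dL"),
    "bicarbonate": (20.0, 28.0, 24.0, 2.0, -1, "mmol/L"),
    "wbc": (5.0, 14.5, 9.0, 2.5, +1, "10^3/uL"),
    "hematocrit": (34.0, 44.0, 38.0, 3.0, -1, "%"),
    "hemoglobin": (11.0, 15.0, 13.0, 1.0, -1, "g/dL"),
}

ACUITY_SCORES = ("pews_total", "acuity_level")

# Attribute -> ordered value vocabulary, normal first.
ASSESSMENT_CATALOG = {
    "work_of_breathing": ("normal", "mild", "moderate", "severe"),
    "level_of_consciousness": ("alert", "drowsy", "lethargic", "unresponsive"),
    "perfusion_cap_refill": ("brisk", "sluggish", "prolonged"),
    "cough": ("none", "dry", "productive"),
    "mobility": ("4", "3", "2", "1"),
    "respiratory_status": ("clear", "diminished", "labored"),
}

RESP_SUPPORT_ATTRS = ("CPAP", "BiPAP", "invasive_ventilation")
VASOPRESSORS = ("epinephrine_infusion", "norepinephrine_infusion",
                "dopamine_infusion")
FLUID_BOLUSES = ("NS_bolus", "LR_bolus")
EMERGENT_PROCEDURES = ("CPR", "rapid_response_activation")
ICU_ONLY_MEDS = ("milrinone_infusion", "vecuronium_infusion")

AGE_BINS = (("<1", 0.0, 1.0), ("1-4", 1.0, 5.0), ("5-11", 5.0, 12.0),
            ("12-17", 12.0, 18.0), (">=18", 18.0, 21.0))
AGE_BIN_LABELS = tuple(b[0] for b in AGE_BINS)

DEFAULT_AGE_DISTRIBUTION = {
    "<1": 0.20, "1-4": 0.30, "5-11": 0.25, "12-17": 0.20, ">=18": 0.05,
}
DEFAULT_DIAGNOSIS_DISTRIBUTION = {
    "respiratory": 0.22, "infectious": 0.16, "neurologic": 0.14,
    "gastrointestinal": 0.14, "cardiac": 0.10, "oncologic": 0.09,
    "other": 0.15,
}

_STUDY_START = pd.Timestamp("2011-01-01")
_STUDY_SPAN_DAYS = 3.5 * 365.0  # admissions spread over 2011 - mid-2014


def age_bin(age_years: float) -> str:
    """Map an age in years to its stratification bin."""
    for label, lo, hi in AGE_BINS:
        if lo <= age_years < hi:
            return label
    return AGE_BINS[-1][0]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic EHR generator.

    Rates are per-encounter totals (split evenly across the elements of each
    category); ``vitals_sampling_interval_hours`` is the mean of the
    exponential inter-observation gap per vital type.  ``effect_size`` is the
    standardized drift (in within-type SD units) reached at the moment of
    ICU transfer; the drift ramps linearly from zero starting
    ``deterioration_onset_hours_before_transfer`` before the transfer.
    """

    n_case_encounters: int = 100
    n_control_encounters: int = 500
    seed: int = 0
    vitals_sampling_interval_hours: float = 2.0
    lab_rate_per_day: float = 4.0
    acuity_rate_per_day: float = 6.0
    assessment_rate_per_day: float = 8.0
    deterioration_onset_hours_before_transfer: float = 8.0
    effect_size: float = 2.0
    missingness_fraction: float = 0.1
    intervention_probability: float = 0.9
    ed_prefix_probability: float = 0.35
    age_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION))
    diagnosis_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_DISTRIBUTION))

    def validate(self) -> None:
        if self.n_case_encounters < 0 or self.n_control_encounters < 0:
            raise ValueError("encounter counts must be >= 0")
        for name in ("vitals_sampling_interval_hours", "lab_rate_per_day",
                     "acuity_rate_per_day", "assessment_rate_per_day",
                     "deterioration_onset_hours_before_transfer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.missingness_fraction <= 1.0:
            raise ValueError("missingness_fraction must lie in [0, 1]")
        if not 0.0 <= self.intervention_probability <= 1.0:
            raise ValueError("intervention_probability must lie in [0, 1]")
        for dist in (self.age_distribution, self.diagnosis_distribution):
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-6):
                raise ValueError("categorical distributions must sum to 1")


@dataclass
class LatentTrajectory:
    """Ground-truth deterioration process for one encounter.

    ``event_time`` is the ICU-transfer time for cases and the floor-departure
    time for controls.  ``severity`` maps hours-to-event to the standardized
    drift in [0, effect_size]: identically 0 for controls, and for cases 0
    earlier than the onset and linearly rising to ``effect_size`` at the
    event.
    """

    encounter_id: str
    is_case: bool
    event_time: pd.Timestamp
    onset_hours: float
    effect_size: float

    def severity(self, hours_to_event):
        scalar = np.ndim(hours_to_event) == 0
        tte = np.asarray(hours_to_event, dtype=float)
        if not self.is_case or self.effect_size == 0:
            out = np.zeros_like(tte)
        else:
            ramp = np.clip(1.0 - tte / self.onset_hours, 0.0, 1.0)
            ramp = np.where(tte < 0, 0.0, ramp)  # defined up to the event
            out = self.effect_size * ramp
        return float(out) if scalar else out


class _EventBuffer:
    """Column-wise accumulator for events; one DataFrame build at the end."""

    def __init__(self) -> None:
        self.parts: list[tuple] = []

    def emit(self, pid: str, eid: str, t_seconds: np.ndarray, category: str,
             attributes, values, unit: str) -> None:
        n = len(t_seconds)
        if n == 0:
            return
        if isinstance(attributes, str):
            attributes = np.full(n, attributes, dtype=object)
        self.parts.append((pid, eid, np.asarray(t_seconds, dtype=np.int64),
                           category, np.asarray(attributes, dtype=object),
                           np.asarray(values, dtype=object), unit))

    def to_frame(self) -> pd.DataFrame:
        if not self.parts:
            from .io import _empty_events
            return _empty_events()
        pid, eid, ts, cat, attr, val, unit = [], [], [], [], [], [], []
        for p, e, t, c, a, v, u in self.parts:
            n = len(t)
            pid.append(np.full(n, p, dtype=object))
            eid.append(np.full(n, e, dtype=object))
            ts.append(t)
            cat.append(np.full(n, c, dtype=object))
            attr.append(a)
            val.append(v)
            unit.append(np.full(n, u, dtype=object))
        events = pd.DataFrame({
            "patient_id": np.concatenate(pid),
            "encounter_id": np.concatenate(eid),
            "timestamp": pd.to_datetime(np.concatenate(ts), unit="s"),
            "category": np.concatenate(cat),
            "attribute": np.concatenate(attr),
            "value": np.concatenate(val),
            "unit": np.concatenate(unit),
        })
        events = events.sort_values(
            ["encounter_id", "timestamp", "category", "attribute"],
            kind="stable").reset_index(drop=True)
        return events[EVENT_COLUMNS]


def _poisson_times(rng: np.random.Generator, rate_per_day: float,
                   duration_hours: float) -> np.ndarray:
    n = rng.poisson(rate_per_day * duration_hours / 24.0)
    return np.sort(rng.uniform(0.0, duration_hours, size=n))


def _renewal_times(rng: np.random.Generator, mean_gap_hours: float,
                   duration_hours: float) -> np.ndarray:
    n_draw = int(duration_hours / mean_gap_hours * 2) + 10
    gaps = rng.exponential(mean_gap_hours, size=n_draw)
    t = np.cumsum(gaps)
    while len(t) and t[-1] < duration_hours:  # pragma: no cover - rare
        extra = np.cumsum(rng.exponential(mean_gap_hours, size=n_draw)) + t[-1]
        t = np.concatenate([t, extra])
    return t[t < duration_hours]


def _sample_categorical(rng: np.random.Generator, dist: dict) -> str:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate(config: GeneratorConfig) -> tuple[Encounters, pd.DataFrame,
                                               list[LatentTrajectory]]:
    """Generate encounters, an event stream, and the latent ground truth.

    Case encounters contain a floor segment followed by an ICU segment and
    (with ``intervention_probability``) at least one intervention event in
    [transfer-2h, transfer+12h]; control encounters are floor-only with at
    least 24 h of floor time.  Deterministic: the same config (including
    seed) yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    buf = _EventBuffer()
    adt_rows: list[tuple] = []
    info_rows: list[tuple] = []
    truth: list[LatentTrajectory] = []

    n_total = config.n_case_encounters + config.n_control_encounters
    for i in range(n_total):
        is_case = i < config.n_case_encounters
        eid = f"E{i:06d}"
        pid = f"P{i:06d}"
        _generate_encounter(rng, config, buf, adt_rows, info_rows, truth,
                            pid, eid, is_case)

    events = buf.to_frame()
    if config.missingness_fraction > 0 and len(events):
        observable = events["category"].isin(
            ("vital", "lab", "acuity", "assessment")).to_numpy()
        drop = rng.random(len(events)) < config.missingness_fraction
        events = events[~(observable & drop)].reset_index(drop=True)

    adt = pd.DataFrame(adt_rows, columns=ADT_COLUMNS)
    adt["start"] = pd.to_datetime(adt["start"])
    adt["end"] = pd.to_datetime(adt["end"])
    info = pd.DataFrame(info_rows, columns=INFO_COLUMNS)
    info["admit_time"] = pd.to_datetime(info["admit_time"])
    return Encounters(adt=adt, info=info), events, truth


def _generate_encounter(rng, config: GeneratorConfig, buf: _EventBuffer,
                        adt_rows, info_rows, truth, pid: str, eid: str,
                        is_case: bool) -> None:
    bin_label = _sample_categorical(rng, config.age_distribution)
    lo, hi = next((b[1], b[2]) for b in AGE_BINS if b[0] == bin_label)
    age = float(np.round(rng.uniform(lo, hi), 2))
    dx = _sample_categorical(rng, config.diagnosis_distribution)

    admit_s = int(_STUDY_START.timestamp()) + int(
        rng.uniform(0, _STUDY_SPAN_DAYS * 86400))
    admit = pd.Timestamp(admit_s, unit="s")

    t = 0.0  # hours since admission
    if rng.random() < config.ed_prefix_probability:
        ed_dur = rng.uniform(2.0, 8.0)
        adt_rows.append((pid, eid, "ED", _ts(admit, t), _ts(admit, t + ed_dur)))
        t += ed_dur
    floor_start = t
    # same floor-duration law for cases and controls: time on the floor
    # itself carries no case/control signal (clean effect_size=0 null)
    floor_dur = rng.uniform(28.0, 120.0)
    floor_end = floor_start + floor_dur
    adt_rows.append((pid, eid, "floor", _ts(admit, floor_start),
                     _ts(admit, floor_end)))
    if is_case:
        icu_dur = rng.uniform(24.0, 96.0)
        adt_rows.append((pid, eid, "ICU", _ts(admit, floor_end),
                         _ts(admit, floor_end + icu_dur)))
    info_rows.append((pid, eid, admit, age, dx))

    event_time = _ts(admit, floor_end)
    traj = LatentTrajectory(
        encounter_id=eid, is_case=is_case, event_time=event_time,
        onset_hours=config.deterioration_onset_hours_before_transfer,
        effect_size=config.effect_size)
    truth.append(traj)

    def sev(times_h: np.ndarray) -> np.ndarray:
        return traj.severity(floor_end - times_h)

    admit_epoch = int(admit.timestamp())

    def seconds(times_h: np.ndarray) -> np.ndarray:
        return admit_epoch + np.round(np.asarray(times_h) * 3600.0).astype(np.int64)

    # --- vitals: renewal process per type over the floor stay
    for name, (base, sd, direction, unit) in VITALS.items():
        tv = floor_start + _renewal_times(
            rng, config.vitals_sampling_interval_hours, floor_dur)
        vals = base + sd * rng.standard_normal(len(tv)) + direction * sd * sev(tv)
        if name == "oxygen_saturation":
            vals = np.minimum(vals, 100.0)
        vals = np.round(np.maximum(vals, 0.0), 1)
        buf.emit(pid, eid, seconds(tv), "vital", name, vals, unit)

    # --- labs: Poisson per analyte, sparse
    per_analyte = config.lab_rate_per_day / len(LABS)
    for name, (low, high, mean, sd, direction, unit) in LABS.items():
        tv = floor_start + _poisson_times(rng, per_analyte, floor_dur)
        vals = mean + sd * rng.standard_normal(len(tv)) + direction * sd * sev(tv)
        vals = np.round(np.maximum(vals, 0.05), 2)
        buf.emit(pid, eid, seconds(tv), "lab", name, vals, unit)

    # --- acuity scores: integers rising with severity
    per_score = config.acuity_rate_per_day / len(ACUITY_SCORES)
    for name in ACUITY_SCORES:
        tv = floor_start + _poisson_times(rng, per_score, floor_dur)
        s = sev(tv)
        if name == "pews_total":
            vals = np.clip(rng.poisson(0.8, size=len(tv)) +
                           np.round(1.5 * s), 0, 9)
        else:
            vals = np.clip(1 + rng.poisson(0.5, size=len(tv)) +
                           np.round(1.0 * s), 1, 5)
        buf.emit(pid, eid, seconds(tv), "acuity", name,
                 vals.astype(float), "score")

    # --- nursing assessments: categorical values shifting toward abnormal
    per_attr = config.assessment_rate_per_day / len(ASSESSMENT_CATALOG)
    for attr, vocab in ASSESSMENT_CATALOG.items():
        tv = floor_start + _poisson_times(rng, per_attr, floor_dur)
        s = sev(tv)
        p_abn = np.clip(0.08 + 0.22 * s, 0.0, 0.92)
        abnormal = rng.random(len(tv)) < p_abn
        depth = rng.binomial(len(vocab) - 2,
                             np.clip(0.25 + 0.25 * s, 0.0, 0.95))
        idx = np.where(abnormal, 1 + depth, 0)
        vals = np.array([vocab[j] for j in idx], dtype=object)
        buf.emit(pid, eid, seconds(tv), "assessment", attr, vals, "")

    # --- interventions around the ICU transfer (cases only)
    if is_case and rng.random() < config.intervention_probability:
        window_lo, window_hi = floor_end - 2.0, floor_end + 12.0
        kind = rng.choice(3, p=[0.5, 0.25, 0.25])
        t_int = rng.uniform(window_lo, window_hi)
        if kind == 0:
            buf.emit(pid, eid, seconds(np.array([t_int])), "resp_support",
                     RESP_SUPPORT_ATTRS[rng.integers(len(RESP_SUPPORT_ATTRS))],
                     np.array(["initiated"], dtype=object), "")
        elif kind == 1:
            buf.emit(pid, eid, seconds(np.array([t_int])), "med",
                     VASOPRESSORS[rng.integers(len(VASOPRESSORS))],
                     np.array([float(np.round(rng.uniform(0.02, 0.5), 3))],
                              dtype=object), "ug/kg/min")
        else:
            buf.emit(pid, eid, seconds(np.array([t_int])), "med",
                     FLUID_BOLUSES[rng.integers(len(FLUID_BOLUSES))],
                     np.array([float(np.round(rng.uniform(20.0, 40.0), 1))],
                              dtype=object), "mL/kg")
        # occasional extras, not guaranteed to satisfy any criterion
        if rng.random() < 0.30:
            buf.emit(pid, eid,
                     seconds(np.array([rng.uniform(window_lo, window_hi)])),
                     "med", FLUID_BOLUSES[rng.integers(len(FLUID_BOLUSES))],
                     np.array([float(np.round(rng.uniform(5.0, 40.0), 1))],
                              dtype=object), "mL/kg")
        if rng.random() < 0.12:
            buf.emit(pid, eid,
                     seconds(np.array([rng.uniform(window_lo, window_hi)])),
                     "med", EMERGENT_PROCEDURES[rng.integers(
                         len(EMERGENT_PROCEDURES))],
                     np.array(["performed"], dtype=object), "")
        if rng.random() < 0.12:
            buf.emit(pid, eid,
                     seconds(np.array([rng.uniform(floor_end,
                                                   window_hi)])),
                     "med", ICU_ONLY_MEDS[rng.integers(len(ICU_ONLY_MEDS))],
                     np.array(["administered"], dtype=object), "")


def _ts(admit: pd.Timestamp, hours: float) -> pd.Timestamp:
    return admit + pd.Timedelta(seconds=int(round(hours * 3600.0)))
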