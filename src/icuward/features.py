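"""Time-windowed feature extraction from irregular clinical event streams.

Each cohort record plus a prediction horizon defines a *prediction point*:
the risk score is computed ``horizon`` hours before the case's ICU transfer
(or the control's floor departure), using only events charted up to that
moment.  Per clinical-element category, events inside a lookback window —
24 h for vitals, 72 h for labs, acuity scores, and nursing assessments —
feed a family of operators:

* vitals: least-squares slope (units/hour), its magnitude, a sign indicator,
  binned C1-C4 category of the MAX/MIN/AVERAGE/NEWEST/OLDEST value, and a
  normalized category histogram;
* labs: (2nd-newest, newest) Low/Normal/High category pair, category
  change/no-change, ratio indicator bins for newest/oldest and
  newest/2nd-newest at >{1.25, 1.5, 2.0, 3.0} and <{0.8, 0.67, 0.5, 0.33},
  a presence indicator, and the last category;
* acuity scores: =0 / >0..>9 threshold indicators for MIN/MAX/NEWEST, the
  full-window and last-6-h slopes with magnitudes, and overlapping
  measurement-count indicators over the last 6 h at >{0, 1, 2, 4, 6, 10};
* assessments: one indicator per attribute-value pair seen in the window
  plus a NEWEST attribute-value indicator per attribute.

Missing data contribute no features (no imputation); element types with
fewer than two points emit no slope features.  Windows are open at both
ends, ``(t_pred - w, t_pred)``: only events strictly before the prediction
time are visible (the hard leakage guarantee), and exactly-stale
observations at the window's far edge are excluded.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .binning import BinningTable

logger = logging.getLogger(__name__)

FEATURE_SETS = ("vitals", "labs", "acuity", "assessments")

_CATEGORY_TO_SET = {"vital": "vitals", "lab": "labs", "acuity": "acuity",
                    "assessment": "assessments"}

RATIO_UPPER = (1.25, 1.5, 2.0, 3.0)
RATIO_LOWER = (0.8, 0.67, 0.5, 0.33)
ACUITY_THRESHOLDS = tuple(range(10))
ACUITY_COUNT_THRESHOLDS = (0, 1, 2, 4, 6, 10)


@dataclass(frozen=True)
class WindowSpec:
    """Lookback windows (hours): 24 for vitals, 72 for everything else, with
    a nested 6 h sub-window for acuity recency features."""

    vitals_hours: float = 24.0
    other_hours: float = 72.0
    sub_window_hours: float = 6.0

    def __post_init__(self):
        if min(self.vitals_hours, self.other_hours,
               self.sub_window_hours) <= 0:
            raise ValueError("window lengths must be positive")


@dataclass(frozen=True)
class PredictionPoint:
    encounter_id: str
    y: int
    horizon_hours: float
    prediction_time: pd.Timestamp


@dataclass
class Instance:
    """A sparse named-feature vector with its binary label and provenance."""

    encounter_id: str
    y: int
    horizon_hours: float
    prediction_time: pd.Timestamp
    features: dict[str, float] = field(default_factory=dict)


def _slope(t: np.ndarray, v: np.ndarray) -> float | None:
    """Least-squares slope in units/hour; None when degenerate."""
    tc = t - t.mean()
    denom = float((tc * tc).sum())
    if denom == 0.0:
        return None
    return float((tc * v).sum() / denom)


def vitals_features(series: dict[str, tuple[np.ndarray, np.ndarray]],
                    binning: BinningTable, age_years: float) -> dict[str, float]:
    """Feature fragment for per-type (times, values) vitals series.

    Times are hours relative to the prediction point (non-positive), sorted;
    stable order resolves duplicate timestamps (newest = last).
    """
    feats: dict[str, float] = {}
    for name, (t, v) in series.items():
        if len(v) == 0:
            continue
        v = np.asarray(v, dtype=float)
        if len(v) >= 2:
            slope = _slope(t, v)
            if slope is not None:
                feats[f"{name} slope"] = slope
                feats[f"{name} slope magnitude"] = abs(slope)
                if slope > 0:
                    feats[f"{name} slope is positive"] = 1.0
                elif slope < 0:
                    feats[f"{name} slope is negative"] = 1.0
        summaries = (("Maximum", float(v.max())), ("Minimum", float(v.min())),
                     ("Average", float(v.mean())), ("Newest", float(v[-1])),
                     ("Oldest", float(v[0])))
        for label, value in summaries:
            cat = binning.vital_category(name, age_years, value)
            feats[f"{label} {name} is {cat}"] = 1.0
        cats = binning.vital_categories(name, age_years, v)
        uniq, counts = np.unique(cats, return_counts=True)
        for cat, n in zip(uniq, counts):
            feats[f"{name} {cat} histogram"] = float(n) / len(v)
    return feats


def lab_features(series: dict[str, tuple[np.ndarray, np.ndarray]],
                 binning: BinningTable) -> dict[str, float]:
    """Feature fragment for per-analyte lab series (times ascending)."""
    feats: dict[str, float] = {}
    for name, (t, v) in series.items():
        if len(v) == 0:
            continue
        v = np.asarray(v, dtype=float)
        cats = [binning.lab_category(name, x) for x in v]
        feats[f"{name} is present"] = 1.0
        feats[f"Last {name} is {cats[-1]}"] = 1.0
        if len(v) < 2:
            continue
        second, newest = cats[-2], cats[-1]
        feats[f"{name} {second}->{newest}"] = 1.0
        changed = "changed" if second != newest else "unchanged"
        feats[f"{name} category {changed}"] = 1.0
        for ref_name, ref in (("oldest", float(v[0])), ("2nd", float(v[-2]))):
            if ref == 0.0:
                continue  # ratio undefined; features omitted
            ratio = float(v[-1]) / ref
            for thr in RATIO_UPPER:
                if ratio > thr:
                    feats[f"{name} newest/{ref_name}>{thr}"] = 1.0
            for thr in RATIO_LOWER:
                if ratio < thr:
                    feats[f"{name} newest/{ref_name}<{thr}"] = 1.0
    return feats


def acuity_features(series: dict[str, tuple[np.ndarray, np.ndarray]],
                    spec: WindowSpec) -> dict[str, float]:
    """Feature fragment for per-score-type acuity series.

    Times are hours relative to the prediction point (non-positive); the
    6 h sub-window selects times in ``(-sub_window_hours, 0]``.
    """
    feats: dict[str, float] = {}
    for name, (t, v) in series.items():
        if len(v) == 0:
            continue
        v = np.asarray(v, dtype=float)
        for label, value in (("Minimum", float(v.min())),
                             ("Maximum", float(v.max())),
                             ("Newest", float(v[-1]))):
            if value == 0.0:
                feats[f"{label} {name} is 0"] = 1.0
            for k in ACUITY_THRESHOLDS:
                if value > k:
                    feats[f"{label} {name}>{k}"] = 1.0
        if len(v) >= 2:
            slope = _slope(t, v)
            if slope is not None:
                feats[f"{name} slope"] = slope
                feats[f"{name} slope magnitude"] = abs(slope)
        sub = t > -spec.sub_window_hours
        n_sub = int(sub.sum())
        if n_sub >= 2:
            slope6 = _slope(t[sub], v[sub])
            if slope6 is not None:
                feats[f"{name} slope last 6h"] = slope6
                feats[f"{name} slope magnitude last 6h"] = abs(slope6)
        for k in ACUITY_COUNT_THRESHOLDS:
            if n_sub > k:
                feats[f"Number of {name} measurements last 6h>{k}"] = 1.0
    return feats


def assessment_features(series: dict[str, tuple[np.ndarray, np.ndarray]]
                        ) -> dict[str, float]:
    """Presence indicators for attribute-value pairs plus a NEWEST indicator
    per attribute (multiplicity is not counted)."""
    feats: dict[str, float] = {}
    for attr, (t, v) in series.items():
        if len(v) == 0:
            continue
        for value in dict.fromkeys(v):  # preserve order, drop duplicates
            feats[f"{attr} is {value}"] = 1.0
        feats[f"Newest {attr} is {v[-1]}"] = 1.0
    return feats


class EventIndex:
    """Per-encounter, per-category, per-attribute time/value arrays.

    Built once from an event stream; prediction points then slice their
    windows with binary search, which keeps repeated featurization across
    horizons cheap.
    """

    def __init__(self, events: pd.DataFrame):
        if len(events):
            self.epoch = events["timestamp"].min()
        else:
            self.epoch = pd.Timestamp("2011-01-01")
        self.by_encounter: dict[str, dict[str, dict[str, tuple]]] = {}
        if len(events) == 0:
            return
        ev = events.sort_values("timestamp", kind="stable")
        hours = ((ev["timestamp"] - self.epoch).dt.total_seconds() / 3600.0
                 ).to_numpy()
        vals = ev["value"].to_numpy()
        # groupby preserves the time-sorted order within each group
        groups = ev.groupby(["encounter_id", "category", "attribute"],
                            sort=False).indices
        for (eid, cat, attr), idx in groups.items():
            t = hours[idx]
            v = vals[idx]
            if cat in ("vital", "lab", "acuity"):
                v = v.astype(float)
            self.by_encounter.setdefault(eid, {}).setdefault(cat, {})[attr] = \
                (t, v)

    def hours(self, ts: pd.Timestamp) -> float:
        return (ts - self.epoch).total_seconds() / 3600.0

    def windowed(self, encounter_id: str, category: str,
                 prediction_time: pd.Timestamp, window_hours: float
                 ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-attribute series within ``(t_pred - w, t_pred)``, with times
        re-expressed as hours relative to the prediction point."""
        tp = self.hours(prediction_time)
        out = {}
        for attr, (t, v) in self.by_encounter.get(encounter_id, {}).get(
                category, {}).items():
            i0 = np.searchsorted(t, tp - window_hours, side="right")
            i1 = np.searchsorted(t, tp, side="left")
            if i1 > i0:
                out[attr] = (t[i0:i1] - tp, v[i0:i1])
        return out


def window_events(events: pd.DataFrame, point: PredictionPoint,
                  spec: WindowSpec | None = None) -> dict[str, pd.DataFrame]:
    """Per-category event lists for one prediction point.

    Applies the category's lookback window ``(t_pred - w, t_pred)``; nothing
    at or after the prediction time ever leaks in.
    """
    spec = spec or WindowSpec()
    enc = events[events["encounter_id"] == point.encounter_id]
    out = {}
    for category in ("vital", "lab", "acuity", "assessment"):
        w = spec.vitals_hours if category == "vital" else spec.other_hours
        lo = point.prediction_time - pd.Timedelta(hours=w)
        sub = enc[(enc["category"] == category) &
                  (enc["timestamp"] > lo) &
                  (enc["timestamp"] < point.prediction_time)]
        out[category] = sub.sort_values("timestamp", kind="stable")
    return out


def featurize_point(index: EventIndex, encounter_id: str,
                    prediction_time: pd.Timestamp, spec: WindowSpec,
                    binning: BinningTable, age_years: float
                    ) -> dict[str, dict[str, float]]:
    """Per-feature-set fragments for one prediction point."""
    return {
        "vitals": vitals_features(
            index.windowed(encounter_id, "vital", prediction_time,
                           spec.vitals_hours), binning, age_years),
        "labs": lab_features(
            index.windowed(encounter_id, "lab", prediction_time,
                           spec.other_hours), binning),
        "acuity": acuity_features(
            index.windowed(encounter_id, "acuity", prediction_time,
                           spec.other_hours), spec),
        "assessments": assessment_features(
            index.windowed(encounter_id, "assessment", prediction_time,
                           spec.other_hours)),
    }


def featurize_cohort(cohort: pd.DataFrame, events, horizon_hours: float,
                     spec: WindowSpec | None = None,
                     binning: BinningTable | None = None
                     ) -> list[tuple[PredictionPoint, dict]]:
    """One (prediction point, per-set fragments) pair per retained record.

    Records whose prediction time precedes floor arrival (horizon exceeding
    the record's floor hours) are dropped and logged.
    """
    if horizon_hours <= 0:
        raise ValueError("horizon must be positive")
    spec = spec or WindowSpec()
    binning = binning or BinningTable.default()
    index = events if isinstance(events, EventIndex) else EventIndex(events)
    out = []
    dropped = 0
    for row in cohort.itertuples(index=False):
        if horizon_hours > row.floor_hours + 1e-9:
            dropped += 1
            continue
        pred_time = row.event_time - pd.Timedelta(hours=horizon_hours)
        point = PredictionPoint(
            encounter_id=row.encounter_id,
            y=1 if row.label == "case" else 0,
            horizon_hours=horizon_hours, prediction_time=pred_time)
        frags = featurize_point(index, row.encounter_id, pred_time, spec,
                                binning, float(row.age_years))
        out.append((point, frags))
    if dropped:
        logger.info("horizon %.1f h: dropped %d records whose prediction "
                    "time precedes floor arrival", horizon_hours, dropped)
    return out


def merge_fragments(frags: dict[str, dict[str, float]],
                    feature_sets=FEATURE_SETS) -> dict[str, float]:
    merged: dict[str, float] = {}
    for fs in feature_sets:
        merged.update(frags[fs])
    return merged


def build_instances(cohort: pd.DataFrame, events, horizon_hours: float,
                    spec: WindowSpec | None = None,
                    binning: BinningTable | None = None,
                    feature_sets=FEATURE_SETS) -> list[Instance]:
    """Build one labeled instance per cohort record at the given horizon."""
    pairs = featurize_cohort(cohort, events, horizon_hours, spec, binning)
    return [Instance(encounter_id=p.encounter_id, y=p.y,
                     horizon_hours=p.horizon_hours,
                     prediction_time=p.prediction_time,
                     features=merge_fragments(f, feature_sets))
            for p, f in pairs]


class FeatureVocabulary:
    """Ordered feature-name -> column-index mapping, fit on training data.

    Evaluation-time feature names absent from the vocabulary are silently
    dropped, so a frozen vocabulary defines the model's input space.
    """

    def __init__(self, names: list[str]):
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def fit(cls, instances: list[Instance]) -> "FeatureVocabulary":
        names = sorted({name for inst in instances for name in inst.features})
        return cls(names)

    def __len__(self) -> int:
        return len(self.names)

    def transform(self, instances: list[Instance]) -> sparse.csr_matrix:
        rows, cols, data = [], [], []
        for i, inst in enumerate(instances):
            for name, value in inst.features.items():
                j = self.index.get(name)
                if j is not None and value != 0.0:
                    rows.append(i)
                    cols.append(j)
                    data.append(float(value))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(instances), len(self.names)))

    def checksum(self) -> str:
        h = hashlib.md5("\n".join(self.names).encode()).hexdigest()
        return h

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, name in enumerate(self.names):
                fh.write(f"{i}\t{name}\n")

    @classmethod
    def from_tsv(cls, path) -> "FeatureVocabulary":
        names = []
        with open(path) as fh:
            for line in fh:
                _, name = line.rstrip("\n").split("\t", 1)
                names.append(name)
        return cls(names)


def labels(instances: list[Instance]) -> np.ndarray:
    return np.array([inst.y for inst in instances], dtype=int)


def save_svmlight(instances: list[Instance], vocabulary: FeatureVocabulary,
                  path) -> None:
    """Write instances in SVMlight sparse format (label, index:value)."""
    from sklearn.datasets import dump_svmlight_file
    X = vocabulary.transform(instances)
    dump_svmlight_file(X, labels(instances), str(path), zero_based=True)


def load_svmlight(path, n_features: int):
    from sklearn.datasets import load_svmlight_file
    X, y = load_svmlight_file(str(path), n_features=n_features,
                              zero_based=True)
    return sparse.csr_matrix(X), y.astype(int)
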