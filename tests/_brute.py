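"""Independent brute-force transcription of the feature-operator families.

Deliberately written as plain loops over (time, value) lists, sharing no
code with icuward.features, so the two can be compared feature-for-feature
on small fixtures.
"""

import numpy as np


def brute_slope(pairs):
    """Ordinary least-squares slope from explicit normal equations."""
    n = len(pairs)
    sx = sum(t for t, _ in pairs)
    sy = sum(v for _, v in pairs)
    sxx = sum(t * t for t, _ in pairs)
    sxy = sum(t * v for t, v in pairs)
    denom = n * sxx - sx * sx
    if denom == 0:
        return None
    return (n * sxy - sx * sy) / denom


def brute_vital_category(boundaries, descending, value):
    idx = 0
    for b in boundaries:
        if value >= b:
            idx += 1
    if descending:
        idx = len(boundaries) - idx
    return ["C1", "C2", "C3", "C4"][idx]


def brute_lab_category(low, high, value):
    if value < low:
        return "Low"
    if value > high:
        return "High"
    return "Normal"


def brute_vitals(name, pairs, boundaries, descending):
    feats = {}
    if not pairs:
        return feats
    values = [v for _, v in pairs]
    if len(pairs) >= 2:
        slope = brute_slope(pairs)
        if slope is not None:
            feats[f"{name} slope"] = slope
            feats[f"{name} slope magnitude"] = abs(slope)
            if slope > 0:
                feats[f"{name} slope is positive"] = 1.0
            if slope < 0:
                feats[f"{name} slope is negative"] = 1.0
    for label, v in [("Maximum", max(values)), ("Minimum", min(values)),
                     ("Average", sum(values) / len(values)),
                     ("Newest", values[-1]), ("Oldest", values[0])]:
        cat = brute_vital_category(boundaries, descending, v)
        feats[f"{label} {name} is {cat}"] = 1.0
    cats = [brute_vital_category(boundaries, descending, v) for v in values]
    for cat in sorted(set(cats)):
        feats[f"{name} {cat} histogram"] = cats.count(cat) / len(cats)
    return feats


def brute_labs(name, pairs, low, high):
    feats = {}
    if not pairs:
        return feats
    values = [v for _, v in pairs]
    cats = [brute_lab_category(low, high, v) for v in values]
    feats[f"{name} is present"] = 1.0
    feats[f"Last {name} is {cats[-1]}"] = 1.0
    if len(values) < 2:
        return feats
    feats[f"{name} {cats[-2]}->{cats[-1]}"] = 1.0
    feats[f"{name} category "
          + ("changed" if cats[-2] != cats[-1] else "unchanged")] = 1.0
    for ref_name, ref in [("oldest", values[0]), ("2nd", values[-2])]:
        if ref == 0:
            continue
        ratio = values[-1] / ref
        for thr in (1.25, 1.5, 2.0, 3.0):
            if ratio > thr:
                feats[f"{name} newest/{ref_name}>{thr}"] = 1.0
        for thr in (0.8, 0.67, 0.5, 0.33):
            if ratio < thr:
                feats[f"{name} newest/{ref_name}<{thr}"] = 1.0
    return feats


def brute_acuity(name, pairs, sub_window_hours=6.0):
    """pairs: (hours relative to prediction time, value), times <= 0."""
    feats = {}
    if not pairs:
        return feats
    values = [v for _, v in pairs]
    for label, v in [("Minimum", min(values)), ("Maximum", max(values)),
                     ("Newest", values[-1])]:
        if v == 0:
            feats[f"{label} {name} is 0"] = 1.0
        for k in range(10):
            if v > k:
                feats[f"{label} {name}>{k}"] = 1.0
    if len(pairs) >= 2:
        slope = brute_slope(pairs)
        if slope is not None:
            feats[f"{name} slope"] = slope
            feats[f"{name} slope magnitude"] = abs(slope)
    recent = [(t, v) for t, v in pairs if t > -sub_window_hours]
    if len(recent) >= 2:
        slope = brute_slope(recent)
        if slope is not None:
            feats[f"{name} slope last 6h"] = slope
            feats[f"{name} slope magnitude last 6h"] = abs(slope)
    for k in (0, 1, 2, 4, 6, 10):
        if len(recent) > k:
            feats[f"Number of {name} measurements last 6h>{k}"] = 1.0
    return feats


def brute_assessments(name, pairs):
    feats = {}
    if not pairs:
        return feats
    for _, v in pairs:
        feats[f"{name} is {v}"] = 1.0
    feats[f"Newest {name} is {pairs[-1][1]}"] = 1.0
    return feats


def assert_features_close(actual, expected):
    assert set(actual) == set(expected), (
        f"feature-name mismatch:\n only actual: {set(actual) - set(expected)}"
        f"\n only expected: {set(expected) - set(actual)}")
    for name in expected:
        np.testing.assert_allclose(actual[name], expected[name], rtol=1e-12,
                                   err_msg=name)
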