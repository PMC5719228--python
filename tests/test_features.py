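"""Feature-operator correctness, windowing, leakage, and vectorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icuward as iw
import icuward.features as F
from icuward.binning import BinningTable

from _brute import (assert_features_close, brute_acuity, brute_assessments,
                    brute_labs, brute_slope, brute_vitals)
from conftest import hours, make_events

BINNING = BinningTable.default()


def series(*pairs, values_dtype=float):
    t = np.array([p[0] for p in pairs], dtype=float)
    v = np.array([p[1] for p in pairs],
                 dtype=object if values_dtype is str else float)
    return (t, v)


class TestWindowing:
    def point(self):
        return F.PredictionPoint("E1", 1, 6.0, hours(42))

    def test_category_windows(self):
        events = make_events([
            ("E1", 42 - 25, "vital", "heart_rate", 100.0),   # beyond 24 h
            ("E1", 42 - 23, "vital", "heart_rate", 110.0),
            ("E1", 42 - 25, "lab", "glucose", 90.0),          # within 72 h
            ("E1", 42 - 73, "lab", "glucose", 85.0),          # beyond 72 h
        ])
        out = iw.window_events(events, self.point())
        assert list(out["vital"]["value"]) == [110.0]
        assert list(out["lab"]["value"]) == [90.0]

    def test_prediction_time_and_later_excluded(self):
        events = make_events([
            ("E1", 41.0, "vital", "heart_rate", 120.0),
            ("E1", 42.0, "vital", "heart_rate", 150.0),
            ("E1", 42.0 + 1 / 3600.0, "vital", "heart_rate", 200.0),
        ])
        out = iw.window_events(events, self.point())
        assert list(out["vital"]["value"]) == [120.0]

    def test_exactly_stale_observation_excluded(self):
        events = make_events([("E1", 42 - 24, "vital", "heart_rate", 100.0)])
        out = iw.window_events(events, self.point())
        assert len(out["vital"]) == 0


class TestVitals:
    def test_slope_exact_line(self):
        feats = F.vitals_features(
            {"heart_rate": series((0, 120.0), (6, 132.0), (12, 144.0))},
            BINNING, age_years=0.5)
        assert feats["heart_rate slope"] == pytest.approx(2.0)
        assert feats["heart_rate slope magnitude"] == pytest.approx(2.0)
        assert feats["heart_rate slope is positive"] == 1.0
        assert "heart_rate slope is negative" not in feats

    def test_histogram_normalizes(self):
        # <1 y boundaries 140/160/180: categories C1, C2, C2, C4
        feats = F.vitals_features(
            {"heart_rate": series((0, 130.0), (1, 150.0), (2, 150.0),
                                  (3, 185.0))}, BINNING, age_years=0.5)
        assert feats["heart_rate C1 histogram"] == pytest.approx(0.25)
        assert feats["heart_rate C2 histogram"] == pytest.approx(0.50)
        assert feats["heart_rate C4 histogram"] == pytest.approx(0.25)
        assert "heart_rate C3 histogram" not in feats

    def test_single_point_emits_no_slope(self):
        feats = F.vitals_features({"heart_rate": series((0, 120.0))},
                                  BINNING, 0.5)
        assert "heart_rate slope" not in feats
        assert feats["Newest heart_rate is C1"] == 1.0

    def test_empty_type_emits_nothing(self):
        assert F.vitals_features({"heart_rate": series()}, BINNING, 0.5) == {}

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.tuples(
        st.floats(0.0, 24.0), st.floats(40.0, 220.0)), min_size=2,
        max_size=50))
    def test_slope_matches_normal_equations(self, pairs):
        pairs = sorted(pairs)
        t = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        feats = F.vitals_features({"heart_rate": (t, v)}, BINNING, 0.5)
        expected = brute_slope(pairs)
        if expected is None:
            assert "heart_rate slope" not in feats
        else:
            assert feats["heart_rate slope"] == pytest.approx(expected,
                                                              abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(40.0, 220.0), min_size=1, max_size=40))
    def test_histogram_sums_to_one(self, values):
        t = np.arange(len(values), dtype=float)
        feats = F.vitals_features({"heart_rate": (t, np.array(values))},
                                  BINNING, 3.0)
        total = sum(v for k, v in feats.items() if k.endswith("histogram"))
        assert total == pytest.approx(1.0)


class TestLabs:
    def test_category_pair_low_to_normal(self):
        feats = F.lab_features({"glucose": series((0, 60.0), (1, 100.0))},
                               BINNING)
        assert feats["glucose Low->Normal"] == 1.0
        assert feats["glucose category changed"] == 1.0
        assert feats["Last glucose is Normal"] == 1.0

    def test_ratio_bins_fire_up_to_observed_ratio(self):
        # newest/oldest = 8/5 = 1.6 -> fires >1.25 and >1.5, not >2.0
        feats = F.lab_features({"wbc": series((0, 5.0), (1, 8.0))}, BINNING)
        assert feats["wbc newest/oldest>1.25"] == 1.0
        assert feats["wbc newest/oldest>1.5"] == 1.0
        assert "wbc newest/oldest>2.0" not in feats
        assert "wbc newest/oldest<0.8" not in feats

    def test_single_measurement_presence_and_last_only(self):
        feats = F.lab_features({"glucose": series((0, 100.0))}, BINNING)
        assert set(feats) == {"glucose is present", "Last glucose is Normal"}

    def test_zero_reference_omits_ratio_features(self):
        feats = F.lab_features({"glucose": series((0, 0.0), (1, 100.0))},
                               BINNING)
        assert not any("newest/oldest" in k for k in feats)
        # 2nd-newest is also the zero value here
        assert not any("newest/2nd" in k for k in feats)


class TestAcuity:
    SPEC = F.WindowSpec()

    def test_all_zero_scores(self):
        feats = F.acuity_features(
            {"pews_total": series((-10, 0.0), (-2, 0.0))}, self.SPEC)
        assert feats["Minimum pews_total is 0"] == 1.0
        assert feats["Maximum pews_total is 0"] == 1.0
        assert feats["Newest pews_total is 0"] == 1.0
        assert not any(">0" in k and "measurements" not in k for k in feats)

    def test_count_indicators_overlap(self):
        feats = F.acuity_features(
            {"pews_total": series((-5, 1.0), (-3, 2.0), (-1, 3.0))},
            self.SPEC)
        for k in (0, 1, 2):
            assert feats[f"Number of pews_total measurements last 6h>{k}"] == 1.0
        assert "Number of pews_total measurements last 6h>4" not in feats

    def test_six_hour_two_point_slope(self):
        feats = F.acuity_features(
            {"pews_total": series((-6.0 + 1e-9, 2.0), (0.0, 5.0))},
            self.SPEC)
        assert feats["pews_total slope last 6h"] == pytest.approx(0.5)

    def test_subwindow_excludes_old_measurements(self):
        feats = F.acuity_features(
            {"pews_total": series((-10, 2.0), (-8, 2.0), (-1, 5.0))},
            self.SPEC)
        assert "pews_total slope last 6h" not in feats
        assert "Number of pews_total measurements last 6h>0" in feats
        assert "Number of pews_total measurements last 6h>1" not in feats


class TestAssessments:
    def test_pair_and_newest_indicators(self):
        feats = F.assessment_features(
            {"mobility": series((-4, "1"), (-2, "2"), values_dtype=str)})
        assert feats["mobility is 1"] == 1.0
        assert feats["mobility is 2"] == 1.0
        assert feats["Newest mobility is 2"] == 1.0
        assert "Newest mobility is 1" not in feats

    def test_presence_not_multiplicity(self):
        feats = F.assessment_features(
            {"cough": series((-4, "productive"), (-2, "productive"),
                             values_dtype=str)})
        assert feats["cough is productive"] == 1.0

    def test_empty_window_empty_fragment(self):
        assert F.assessment_features({}) == {}


class TestBruteForceAgreement:
    """Full extraction on a hand-built fixture equals an independent
    transcription of the operator families, feature for feature."""

    def test_ten_event_fixture(self):
        vit = [(-20.0, 150.0), (-10.0, 165.0), (-1.0, 185.0)]
        lab = [(-30.0, 5.0), (-4.0, 8.0)]
        acu = [(-7.0, 1.0), (-5.0, 2.0), (-1.0, 4.0)]
        asm = [(-3.0, "productive"), (-1.0, "dry")]
        assert len(vit) + len(lab) + len(acu) + len(asm) == 10

        actual = {}
        actual.update(F.vitals_features(
            {"heart_rate": series(*vit)}, BINNING, age_years=0.5))
        actual.update(F.lab_features({"wbc": series(*lab)}, BINNING))
        actual.update(F.acuity_features({"pews_total": series(*acu)},
                                        F.WindowSpec()))
        actual.update(F.assessment_features(
            {"cough": series(*asm, values_dtype=str)}))

        expected = {}
        expected.update(brute_vitals("heart_rate", vit,
                                     [140.0, 160.0, 180.0], False))
        expected.update(brute_labs("wbc", lab, 5.0, 14.5))
        expected.update(brute_acuity("pews_total", acu))
        expected.update(brute_assessments("cough", asm))
        assert_features_close(actual, expected)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.data())
    def test_random_windows_agree(self, data):
        n = data.draw(st.integers(0, 8))
        vit = sorted((data.draw(st.floats(-24.0, 0.0)),
                      data.draw(st.floats(50.0, 220.0))) for _ in range(n))
        m = data.draw(st.integers(0, 6))
        lab = sorted((data.draw(st.floats(-72.0, 0.0)),
                      data.draw(st.floats(0.5, 30.0))) for _ in range(m))
        actual = {}
        actual.update(F.vitals_features({"heart_rate": series(*vit)}
                                        if vit else {}, BINNING, 7.0))
        actual.update(F.lab_features({"wbc": series(*lab)} if lab else {},
                                     BINNING))
        expected = {}
        expected.update(brute_vitals("heart_rate", vit,
                                     [120.0, 140.0, 160.0], False))
        expected.update(brute_labs("wbc", lab, 5.0, 14.5))
        assert_features_close(actual, expected)


class TestInstances:
    def test_prediction_time_is_event_minus_horizon(self, small_cohort,
                                                    small_index):
        inst = iw.build_instances(small_cohort.head(5), small_index, 6.0)
        for i, row in zip(inst, small_cohort.head(5).itertuples()):
            assert i.prediction_time == row.event_time - pd.Timedelta(hours=6)

    def test_conservation_when_no_drops(self, small_cohort, small_index):
        inst = iw.build_instances(small_cohort, small_index, 6.0)
        assert len(inst) == len(small_cohort)  # all floor stays exceed 6 h

    def test_horizon_exceeding_floor_time_drops_record(self, small_cohort,
                                                       small_index):
        cohort = small_cohort.copy()
        cohort.loc[cohort.index[0], "floor_hours"] = 4.0
        inst = iw.build_instances(cohort, small_index, 6.0)
        assert len(inst) == len(cohort) - 1

    def test_order_invariance_under_event_permutation(self, small_dataset):
        _, _, events, _ = small_dataset
        sub = events[events["encounter_id"] == events["encounter_id"].iloc[0]]
        cohort = pd.DataFrame([{
            "encounter_id": sub["encounter_id"].iloc[0], "label": "control",
            "event_time": sub["timestamp"].max(), "floor_hours": 48.0,
            "age_years": 3.0, "diagnosis_group": "other"}])
        shuffled = sub.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = iw.build_instances(cohort, sub, 6.0)[0].features
        b = iw.build_instances(cohort, shuffled, 6.0)[0].features
        assert a == b

    def test_leakage_guard(self, small_cohort, small_dataset):
        """Perturbing every event at or after the prediction time leaves all
        feature vectors unchanged."""
        _, _, events, _ = small_dataset
        horizon = 6.0
        baseline = iw.build_instances(small_cohort, events, horizon)
        pred_time = dict(zip(small_cohort["encounter_id"],
                             small_cohort["event_time"]
                             - pd.Timedelta(hours=horizon)))
        perturbed = events.copy()
        cutoff = perturbed["encounter_id"].map(pred_time)
        post = perturbed["timestamp"] >= cutoff
        numeric = pd.to_numeric(perturbed["value"], errors="coerce")
        new_vals = perturbed["value"].copy()
        new_vals[post & numeric.notna()] = 9999.0
        perturbed["value"] = new_vals
        after = iw.build_instances(small_cohort, perturbed, horizon)
        for x, z in zip(baseline, after):
            assert x.features == z.features


class TestVocabulary:
    def test_unseen_feature_dropped(self):
        train = [F.Instance("E1", 1, 6.0, hours(0), {"a": 1.0, "b": 2.0}),
                 F.Instance("E2", 0, 6.0, hours(0), {"b": 1.0})]
        vocab = F.FeatureVocabulary.fit(train)
        test = [F.Instance("E3", 1, 6.0, hours(0), {"a": 3.0, "zz": 7.0})]
        X = vocab.transform(test)
        assert X.shape == (1, 2)
        assert X.toarray().tolist() == [[3.0, 0.0]]

    def test_tsv_roundtrip(self, tmp_path):
        vocab = F.FeatureVocabulary(["a b", "c>1.5", "d"])
        vocab.to_tsv(tmp_path / "vocab.tsv")
        back = F.FeatureVocabulary.from_tsv(tmp_path / "vocab.tsv")
        assert back.names == vocab.names
        assert back.checksum() == vocab.checksum()

    def test_svmlight_roundtrip(self, tmp_path):
        train = [F.Instance("E1", 1, 6.0, hours(0), {"a": 1.5, "b": 2.0}),
                 F.Instance("E2", 0, 6.0, hours(0), {"b": -1.0})]
        vocab = F.FeatureVocabulary.fit(train)
        F.save_svmlight(train, vocab, tmp_path / "train.svmlight")
        X, y = F.load_svmlight(tmp_path / "train.svmlight", len(vocab))
        np.testing.assert_allclose(X.toarray(),
                                   vocab.transform(train).toarray())
        assert y.tolist() == [1, 0]
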