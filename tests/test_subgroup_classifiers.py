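import numpy as np
import pandas as pd
import pytest

import mlclust as m
from mlclust.subgroup_classifiers import LabeledFrame
from oracles import best_conjunction_brute, best_univariate_brute


def frame_of(features: dict, labels, cohort=None):
    feats = pd.DataFrame(features)
    labels = pd.Series(labels, index=feats.index, dtype=bool)
    cohort = pd.Series(cohort if cohort is not None else ["c1"] * len(feats),
                       index=feats.index)
    return LabeledFrame(feats, labels, cohort)


class TestEvaluate:
    def test_counting_example(self, rng):
        # 10 positives, rule fires on 9; 20 negatives, fires on 2
        values = np.concatenate([np.full(9, 25.0), [5.0],
                                 np.full(18, 5.0), [25.0, 25.0]])
        labels = [True] * 10 + [False] * 20
        frame = frame_of({"ADAS13": values}, labels)
        clf = m.CutoffClassifier((m.CutoffCondition("ADAS13", ">", 19.0),))
        sens, spec = m.evaluate_classifier(clf, frame)
        assert sens == pytest.approx(90.0)
        assert spec == pytest.approx(90.0)

    def test_always_firing_rule(self):
        frame = frame_of({"x": [1.0, 2.0, 3.0, 4.0]}, [True, True, False, False])
        clf = m.CutoffClassifier((m.CutoffCondition("x", ">", -99.0),))
        assert m.evaluate_classifier(clf, frame) == (100.0, 0.0)

    def test_missing_feature_values_excluded(self):
        frame = frame_of({"x": [10.0, np.nan, 1.0, 2.0]},
                         [True, True, False, False])
        clf = m.CutoffClassifier((m.CutoffCondition("x", ">", 5.0),))
        sens, spec = m.evaluate_classifier(clf, frame)
        assert sens == 100.0  # the NaN positive is excluded, not counted FN
        assert spec == 100.0

    def test_single_class_frame_undefined(self):
        frame = frame_of({"x": [1.0, 2.0]}, [True, True])
        clf = m.CutoffClassifier((m.CutoffCondition("x", ">", 1.5),))
        with pytest.raises(m.UndefinedStatistic):
            m.evaluate_classifier(clf, frame)

    def test_confusion_identities(self, rng):
        values = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        if not labels.any() or labels.all():
            labels[:2] = [True, False]
        frame = frame_of({"x": values}, labels)
        clf = m.CutoffClassifier((m.CutoffCondition("x", ">", 0.0),))
        sens, spec = m.evaluate_classifier(clf, frame)
        fires = values > 0.0
        assert sens == pytest.approx(100 * (fires & labels).sum() / labels.sum())
        assert spec == pytest.approx(100 * (~fires & ~labels).sum() / (~labels).sum())


class TestCandidateThresholds:
    def test_midpoints(self):
        assert m.candidate_thresholds([1, 2, 4]).tolist() == [1.5, 3.0]

    def test_single_value_empty(self):
        assert m.candidate_thresholds([5]).size == 0
        assert m.candidate_thresholds([5, 5, 5]).size == 0

    def test_count_is_n_distinct_minus_one(self, rng):
        values = rng.integers(0, 30, 100).astype(float)
        expected = np.unique(values).size - 1
        assert m.candidate_thresholds(values).size == expected

    def test_no_confusion_table_is_missed_by_midpoints(self, rng):
        """Scanning midpoints reaches every confusion table that scanning
        all observed values +- epsilon can reach."""
        values = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        tables = set()
        for t in np.concatenate([values - 1e-9, values + 1e-9]):
            fires = values > t
            tables.add(((fires & labels).sum(), (fires & ~labels).sum()))
        mid_tables = set()
        for t in np.concatenate([m.candidate_thresholds(values),
                                 [values.min() - 1, values.max() + 1]]):
            fires = values > t
            mid_tables.add(((fires & labels).sum(), (fires & ~labels).sum()))
        assert tables <= mid_tables


class TestSearchUnivariate:
    def test_perfectly_separable(self):
        frame = frame_of({"x": [1.0, 2.0, 3.0, 11.0, 12.0, 13.0]},
                         [False] * 3 + [True] * 3)
        clf = m.search_univariate("x", frame, ">")
        assert clf.metrics["train"] == (100.0, 100.0)
        assert 3.0 < clf.conditions[0].threshold < 11.0

    def test_matches_exhaustive_oracle_on_random_labels(self, rng):
        values = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        frame = frame_of({"x": values}, labels)
        clf = m.search_univariate("x", frame, ">")
        t, j, sens, spec = best_univariate_brute(values, labels, ">")
        assert clf.conditions[0].threshold == pytest.approx(t)
        train_j = (clf.metrics["train"][0] + clf.metrics["train"][1]) / 100 - 1
        assert train_j == pytest.approx(j, abs=1e-12)
        assert train_j < 0.35  # random labels: little signal

    def test_reversed_direction_mirrors_negated_values(self, rng):
        values = rng.normal(size=80)
        labels = values + rng.normal(0, 0.5, 80) > 0
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        fwd = m.search_univariate("x", frame_of({"x": values}, labels), ">")
        rev = m.search_univariate("x", frame_of({"x": -values}, labels), "<")
        assert fwd.metrics["train"] == pytest.approx(rev.metrics["train"])

    def test_degenerate_labels_rejected(self):
        frame = frame_of({"x": [1.0, 2.0]}, [True, True])
        with pytest.raises(m.UndefinedStatistic):
            m.search_univariate("x", frame, ">")


class TestSearchConjunction:
    def test_and_shaped_data_needs_both_conditions(self):
        """Positives sit in the upper-right quadrant only; each single
        feature is imperfect but the conjunction is exact."""
        g = np.array([[0, 0], [0, 1], [1, 0], [1, 1]]).repeat(10, axis=0)
        rng = np.random.default_rng(0)
        x = g[:, 0] * 10 + rng.uniform(0, 1, 40)
        y = g[:, 1] * 10 + rng.uniform(0, 1, 40)
        labels = (g[:, 0] == 1) & (g[:, 1] == 1)
        frame = frame_of({"x": x, "y": y}, labels)
        conj = m.search_conjunction("x", "y", frame)
        assert conj.metrics["train"] == (100.0, 100.0)
        for feat in ("x", "y"):
            uni = m.search_univariate(feat, frame, ">")
            assert uni.metrics["train"][1] < 100.0  # specificity imperfect

    def test_matches_brute_force_grid(self, rng):
        v1 = rng.integers(0, 40, 120).astype(float)
        v2 = rng.integers(0, 40, 120).astype(float)
        labels = (v1 + v2 + rng.normal(0, 10, 120)) > 40
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        frame = frame_of({"a": v1, "b": v2}, labels)
        conj = m.search_conjunction("a", "b", frame)
        t1, t2, j = best_conjunction_brute(v1, v2, labels)
        assert conj.conditions[0].threshold == pytest.approx(t1)
        assert conj.conditions[1].threshold == pytest.approx(t2)
        train_j = sum(conj.metrics["train"]) / 100 - 1
        assert train_j == pytest.approx(j, abs=1e-12)

    def test_conjunction_never_below_constituent_at_same_threshold(self, rng):
        v1 = rng.normal(size=100)
        v2 = rng.normal(size=100)
        labels = v1 + v2 > 0
        frame = frame_of({"a": v1, "b": v2}, labels)
        conj = m.search_conjunction("a", "b", frame)
        uni = m.search_univariate("a", frame, ">")
        conj_j = sum(conj.metrics["train"])
        uni_j = sum(uni.metrics["train"])
        assert conj_j >= uni_j - 1e-9


class TestCrossCohortValidate:
    def test_same_distribution_metrics_agree(self, rng):
        def draw(n, tag):
            v = np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)])
            labels = [False] * n + [True] * n
            return frame_of({"x": v}, labels, [tag] * (2 * n))

        train = draw(120, "study-1")
        test = draw(120, "study-2")
        clf = m.search_univariate("x", train, ">")
        out = m.cross_cohort_validate(clf, train, test)
        for metric in ("sensitivity", "specificity"):
            p = out["train"][metric] / 100
            se = 100 * np.sqrt(p * (1 - p) / 120)
            assert abs(out["train"][metric] - out["test"][metric]) < 3 * se + 1e-9

    def test_flipped_labels_swap_sensitivity_and_specificity(self):
        values = [1.0, 2.0, 10.0, 11.0, 1.5, 10.5]
        labels = [False, False, True, True, False, True]
        train = frame_of({"x": values}, labels, ["a"] * 6)
        flipped = frame_of({"x": values}, [not l for l in labels], ["b"] * 6)
        clf = m.CutoffClassifier((m.CutoffCondition("x", ">", 5.0),))
        out = m.cross_cohort_validate(clf, train, flipped)
        assert out["train"]["sensitivity"] == pytest.approx(
            100 - out["test"]["specificity"])
        assert out["train"]["specificity"] == pytest.approx(
            100 - out["test"]["sensitivity"])

    def test_overlapping_cohorts_rejected(self):
        a = frame_of({"x": [1.0, 2.0]}, [True, False], ["same", "same"])
        clf = m.CutoffClassifier((m.CutoffCondition("x", ">", 1.5),))
        with pytest.raises(m.ValidationError):
            m.cross_cohort_validate(clf, a, a)


def test_classifier_constraints():
    with pytest.raises(m.ConfigurationError):
        m.CutoffClassifier(())
    with pytest.raises(m.ConfigurationError):
        m.CutoffClassifier((m.CutoffCondition("x", ">", 1.0),
                            m.CutoffCondition("x", ">", 2.0)))
    clf = m.CutoffClassifier((m.CutoffCondition("ADAS11", ">", 10.5),
                              m.CutoffCondition("ADAS13", ">", 19.0)))
    assert clf.describe() == "ADAS11 > 10.5 AND ADAS13 > 19"
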