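"""Subgroup-discovery cut-off classifiers for rapid decliners.

The target subgroup (rapid decliners, with the unclustered remainder
folded into the negative class) is described by interpretable threshold
rules: a single cut-off on one cognitive test, or the conjunction of two
cut-offs.  Candidate thresholds are the midpoints between consecutive
distinct observed values — no achievable confusion table is missed by
scanning them — and the search maximises Youden's J (sensitivity +
specificity - 1), breaking ties toward higher specificity.  Classifiers
are developed on one study cohort and validated frozen on the other.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatistic, ValidationError

logger = logging.getLogger(__name__)

RELATIONS = (">", "<")


@dataclass(frozen=True)
class CutoffCondition:
    feature: str
    relation: str
    threshold: float

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ConfigurationError(f"unknown relation {self.relation!r}")

    def mask(self, values: np.ndarray) -> np.ndarray:
        return values > self.threshold if self.relation == ">" else values < self.threshold


@dataclass
class CutoffClassifier:
    """A conjunction of one or two cut-off conditions on distinct tests,
    with per-cohort sensitivity/specificity attached after evaluation."""

    conditions: tuple[CutoffCondition, ...]
    metrics: dict = field(default_factory=dict)  # cohort tag -> (sens, spec)

    def __post_init__(self):
        if not 1 <= len(self.conditions) <= 2:
            raise ConfigurationError("a cut-off classifier has 1 or 2 conditions")
        feats = [c.feature for c in self.conditions]
        if len(set(feats)) != len(feats):
            raise ConfigurationError("conditions must be on distinct tests")

    def describe(self) -> str:
        return " AND ".join(f"{c.feature} {c.relation} {c.threshold:g}"
                            for c in self.conditions)

    def fires(self, frame: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(frame), dtype=bool)
        for c in self.conditions:
            if c.feature not in frame.columns:
                raise ConfigurationError(f"feature {c.feature!r} missing")
            mask &= c.mask(frame[c.feature].to_numpy(dtype=float))
        return mask

    def to_json(self, path) -> None:
        doc = {
            "conditions": [[c.feature, c.relation, c.threshold]
                           for c in self.conditions],
            "metrics": {k: list(v) for k, v in self.metrics.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


@dataclass
class LabeledFrame:
    """Per-subject feature values, the binary rapid/not-rapid label, and
    the study-cohort tag of every subject."""

    features: pd.DataFrame
    labels: pd.Series
    cohort: pd.Series

    def __post_init__(self):
        if not self.features.index.equals(self.labels.index):
            raise ConfigurationError("features and labels must share an index")
        if not self.features.index.equals(self.cohort.index):
            raise ConfigurationError("features and cohort must share an index")

    def restrict(self, cohort_tag: str) -> "LabeledFrame":
        keep = self.cohort == cohort_tag
        return LabeledFrame(self.features[keep], self.labels[keep],
                            self.cohort[keep])


def make_labeled_frame(cohort, clustering, features, positive_label: str,
                       ) -> LabeledFrame:
    """Build a LabeledFrame from a cohort and a clustering: subjects in
    ``positive_label`` are positives and everyone else — including the
    unclustered — is negative."""
    from .cohort_io import build_layers

    layer1, _ = build_layers(cohort, baseline_names=list(features))
    subjects = clustering.subjects or cohort.subjects
    label_of = dict(zip(subjects, clustering.labels))
    labels = pd.Series([label_of.get(s) == positive_label for s in layer1.subjects],
                       index=layer1.data.index)
    tags = pd.Series([cohort.cohort_label.get(s, "") for s in layer1.subjects],
                     index=layer1.data.index)
    return LabeledFrame(layer1.data, labels, tags)


# ---------------------------------------------------------------------------
# Evaluation and search
# ---------------------------------------------------------------------------

def _confusion(fires: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(fires & y))
    fn = int(np.sum(~fires & y))
    tn = int(np.sum(~fires & ~y))
    fp = int(np.sum(fires & ~y))
    return tp, fn, tn, fp


def evaluate_classifier(clf: CutoffClassifier, frame: LabeledFrame
                        ) -> tuple[float, float]:
    """Sensitivity and specificity (percent) of ``clf`` on ``frame``.

    Subjects missing any feature the classifier tests are excluded from
    the evaluation (count logged).  A frame without positives or without
    negatives leaves the corresponding metric undefined.
    """
    feats = [c.feature for c in clf.conditions]
    sub = frame.features[feats]
    complete = sub.notna().all(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("evaluate_classifier: excluded %d subject(s) with missing "
                    "feature values", n_excluded)
    y = frame.labels.to_numpy(dtype=bool)[complete]
    fires = clf.fires(sub[complete])
    tp, fn, tn, fp = _confusion(fires, y)
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedStatistic("need both positives and negatives to score")
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints between consecutive distinct observed values."""
    distinct = np.unique(np.asarray(values, dtype=float))
    distinct = distinct[~np.isnan(distinct)]
    if distinct.size < 2:
        return np.array([])
    return (distinct[:-1] + distinct[1:]) / 2.0


def _complete(frame: LabeledFrame, feats) -> tuple[pd.DataFrame, np.ndarray]:
    sub = frame.features[list(feats)]
    keep = sub.notna().all(axis=1).to_numpy()
    return sub[keep], frame.labels.to_numpy(dtype=bool)[keep]


def _sens_spec(fires: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tp, fn, tn, fp = _confusion(fires, y)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def search_univariate(feature: str, frame: LabeledFrame,
                      direction: str = ">") -> CutoffClassifier:
    """Exhaustive scan of one feature's candidate thresholds for the
    cut-off maximising Youden's J; ties break toward higher specificity,
    then toward the lower threshold."""
    if direction not in RELATIONS:
        raise ConfigurationError(f"direction must be one of {RELATIONS}")
    sub, y = _complete(frame, [feature])
    if not y.any() or y.all():
        raise UndefinedStatistic("labels are degenerate on the complete cases")
    values = sub[feature].to_numpy(dtype=float)
    thresholds = candidate_thresholds(values)
    if thresholds.size == 0:
        raise ConfigurationError(f"feature {feature!r} has fewer than two "
                                 "distinct values")
    best = None
    for t in thresholds:
        fires = values > t if direction == ">" else values < t
        sens, spec = _sens_spec(fires, y)
        key = (-(sens + spec - 1.0), -spec, t)
        if best is None or key < best[0]:
            best = (key, t, (sens, spec))
    _, t, (sens, spec) = best
    clf = CutoffClassifier((CutoffCondition(feature, direction, float(t)),))
    clf.metrics["train"] = (100.0 * sens, 100.0 * spec)
    return clf


def search_conjunction(f1: str, f2: str, frame: LabeledFrame,
                       directions: tuple[str, str] = (">", ">")
                       ) -> CutoffClassifier:
    """Grid search over the Cartesian product of both features' candidate
    thresholds for the best AND-combination under Youden's J; ties break
    toward higher specificity, then lower first and second thresholds."""
    if f1 == f2:
        raise ConfigurationError("conjunction features must be distinct")
    sub, y = _complete(frame, [f1, f2])
    if not y.any() or y.all():
        raise UndefinedStatistic("labels are degenerate on the complete cases")
    v1 = sub[f1].to_numpy(dtype=float)
    v2 = sub[f2].to_numpy(dtype=float)
    t1 = candidate_thresholds(v1)
    t2 = candidate_thresholds(v2)
    if t1.size == 0 or t2.size == 0:
        raise ConfigurationError("both features need >= 2 distinct values")

    m1 = (v1[:, None] > t1[None, :]) if directions[0] == ">" else (v1[:, None] < t1[None, :])
    m2 = (v2[:, None] > t2[None, :]) if directions[1] == ">" else (v2[:, None] < t2[None, :])
    pos1 = (m1 & y[:, None]).astype(np.float64)
    neg1 = (m1 & ~y[:, None]).astype(np.float64)
    tp = pos1.T @ m2.astype(np.float64)              # T1 x T2
    fp = neg1.T @ m2.astype(np.float64)
    n_pos = float(y.sum())
    n_neg = float((~y).sum())
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    j = sens + spec - 1.0

    flat = np.column_stack([
        -j.ravel(), -spec.ravel(),
        np.repeat(t1, t2.size), np.tile(t2, t1.size),
    ])
    order = np.lexsort((flat[:, 3], flat[:, 2], flat[:, 1], flat[:, 0]))
    best = order[0]
    i1, i2 = divmod(best, t2.size)
    clf = CutoffClassifier((
        CutoffCondition(f1, directions[0], float(t1[i1])),
        CutoffCondition(f2, directions[1], float(t2[i2])),
    ))
    clf.metrics["train"] = (100.0 * sens[i1, i2], 100.0 * spec[i1, i2])
    return clf


def cross_cohort_validate(clf: CutoffClassifier, train_frame: LabeledFrame,
                          test_frame: LabeledFrame) -> dict:
    """Score a frozen classifier on the training and validation cohorts
    side by side.  The two frames must carry disjoint cohort tags."""
    train_tags = set(train_frame.cohort.unique())
    test_tags = set(test_frame.cohort.unique())
    if train_tags & test_tags:
        raise ValidationError(f"cohort tags overlap: {train_tags & test_tags}")
    out = {}
    for name, fr in (("train", train_frame), ("test", test_frame)):
        sens, spec = evaluate_classifier(clf, fr)
        out[name] = {"sensitivity": sens, "specificity": spec,
                     "cohorts": sorted(fr.cohort.unique())}
        clf.metrics[name] = (sens, spec)
    return out


def metrics_frame(classifiers: list[CutoffClassifier]) -> pd.DataFrame:
    """Side-by-side train/test metrics for a list of classifiers."""
    rows = []
    for clf in classifiers:
        row = {"classifier": clf.describe()}
        for which in ("train", "test"):
            if which in clf.metrics:
                row[f"{which}_sensitivity"] = clf.metrics[which][0]
                row[f"{which}_specificity"] = clf.metrics[which][1]
        rows.append(row)
    return pd.DataFrame(rows)
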