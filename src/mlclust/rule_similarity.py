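"""Example similarity tables (EST) from rule-ensemble coverage.

Instance similarity is defined through an artificial classification
task: the original instances form the positive class and per-column
randomized copies of them (marginals preserved, between-descriptor
correlations destroyed) form the negative class.  A rule learner fitted
to this task emits many conjunctive threshold rules that describe
regions where real data are denser than the randomized background;
instances covered by many common rules are similar.  The EST entry
``x_ij`` is the proportion of rules covering both ``i`` and ``j``, with
the convention ``x_ii = 1``.

The rule learner here is an ensemble of bagged depth-limited decision
trees on the original-vs-randomized task; every root-to-leaf path whose
leaf is positive-enriched on its training resample is one rule.  This is
the random-forest-proximity style of similarity with all knobs exposed
in :class:`RuleLearnerParams`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, EvaluationError

logger = logging.getLogger(__name__)

RELATIONS = ("<=", ">")


@dataclass(frozen=True)
class Condition:
    """One threshold condition ``descriptor <= t`` or ``descriptor > t``."""

    descriptor: str
    relation: str
    threshold: float

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ConfigurationError(f"unknown relation {self.relation!r}")
        if not np.isfinite(self.threshold):
            raise ConfigurationError("rule thresholds must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.relation == "<=" else value > self.threshold


@dataclass(frozen=True)
class Rule:
    """A conjunction of threshold conditions, at most one per
    (descriptor, relation) pair (an interval on a descriptor is the pair
    of its tightest lower and upper bounds)."""

    conditions: tuple[Condition, ...]

    def __post_init__(self):
        if len(self.conditions) == 0:
            raise ConfigurationError("a rule needs at least one condition")
        keys = [(c.descriptor, c.relation) for c in self.conditions]
        if len(set(keys)) != len(keys):
            raise ConfigurationError(
                "duplicate (descriptor, relation) condition in rule")

    def covers_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Boolean coverage of every row of ``frame``."""
        mask = np.ones(len(frame), dtype=bool)
        for c in self.conditions:
            if c.descriptor not in frame.columns:
                raise EvaluationError(f"instance lacks descriptor {c.descriptor!r}")
            col = frame[c.descriptor].to_numpy(dtype=float)
            mask &= (col <= c.threshold) if c.relation == "<=" else (col > c.threshold)
        return mask


def rule_covers(rule: Rule, instance) -> bool:
    """True iff every condition of ``rule`` holds on ``instance``
    (a mapping or Series of descriptor -> value)."""
    for c in rule.conditions:
        if c.descriptor not in instance:
            raise EvaluationError(f"instance lacks descriptor {c.descriptor!r}")
        if not c.holds(float(instance[c.descriptor])):
            return False
    return True


@dataclass(frozen=True)
class RuleLearnerParams:
    """Knobs of the default rule learner: number of bagged trees, tree
    depth, feature subsampling ('sqrt' or a fraction), and the size of
    the randomized negative class (None means balanced, m = N)."""

    n_trees: int = 100
    max_depth: int = 4
    max_features: object = "sqrt"
    n_negatives: int | None = None


@dataclass
class RuleEnsemble:
    """A list of rules plus the learner provenance needed to rerun it."""

    rules: list[Rule]
    provenance: dict = field(default_factory=dict)

    @property
    def R(self) -> int:
        return len(self.rules)

    def to_json(self, path) -> None:
        doc = {
            "provenance": self.provenance,
            "rules": [
                [[c.descriptor, c.relation, c.threshold] for c in r.conditions]
                for r in self.rules
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RuleEnsemble":
        with open(path) as fh:
            doc = json.load(fh)
        rules = [
            Rule(tuple(Condition(d, rel, t) for d, rel, t in conds))
            for conds in doc["rules"]
        ]
        return cls(rules=rules, provenance=doc.get("provenance", {}))


@dataclass
class SimilarityTable:
    """Symmetric N x N table of rule-coverage similarities in [0, 1]."""

    x: np.ndarray
    subjects: list[str]
    layer_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != self.x.shape[1]:
            raise ConfigurationError("similarity table must be square")
        if len(self.subjects) != self.x.shape[0]:
            raise ConfigurationError("subject list does not match table size")
        if not np.array_equal(self.x, self.x.T):
            raise ConfigurationError("similarity table must be symmetric")
        if np.nanmin(self.x) < 0.0 or np.nanmax(self.x) > 1.0:
            raise ConfigurationError("similarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.x, index=self.subjects, columns=self.subjects).to_csv(
            path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, layer_id: str = "") -> "SimilarityTable":
        frame = pd.read_csv(path, index_col="subject_id")
        return cls(x=frame.to_numpy(dtype=float),
                   subjects=[str(s) for s in frame.index], layer_id=layer_id)


# ---------------------------------------------------------------------------
# Negatives, rule induction, EST
# ---------------------------------------------------------------------------

def randomize_instances(matrix: np.ndarray, m: int, seed) -> np.ndarray:
    """Assemble ``m`` negative instances by sampling each column
    independently from its own empirical values (bootstrap per column).
    Marginal distributions are preserved, between-descriptor structure is
    destroyed."""
    x = np.asarray(matrix, dtype=float)
    if m <= 0:
        raise ConfigurationError("need at least one negative instance")
    if np.isnan(x).any():
        raise ConfigurationError("randomize_instances requires an imputed layer")
    rng = np.random.default_rng(seed)
    neg = np.empty((m, x.shape[1]), dtype=float)
    for j in range(x.shape[1]):
        neg[:, j] = rng.choice(x[:, j], size=m, replace=True)
    return neg


def _paths_from_tree(tree, feature_names, strict: bool) -> list[Rule]:
    """Extract one rule per positive-enriched leaf of a fitted tree.

    A leaf qualifies when its positive coverage rate on the training
    resample exceeds (strictly, or weakly when ``strict`` is False) its
    negative coverage rate.  Conditions along the path are collapsed to
    the tightest bound per (feature, relation).
    """
    t = tree.tree_
    # class totals over the resample, from the root's weighted counts
    root = t.value[0, 0] * t.weighted_n_node_samples[0] / max(t.value[0, 0].sum(), 1e-300)
    total_neg, total_pos = float(root[0]), float(root[1])
    rules: list[Rule] = []

    def descend(node: int, bounds: dict):
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node, 0] * t.weighted_n_node_samples[node]
            counts = counts / max(t.value[node, 0].sum(), 1e-300)
            pos_rate = counts[1] / total_pos if total_pos else 0.0
            neg_rate = counts[0] / total_neg if total_neg else 0.0
            ok = pos_rate > neg_rate if strict else pos_rate >= neg_rate
            if ok and bounds:
                conds = tuple(
                    Condition(name, rel, thr)
                    for (name, rel), thr in sorted(bounds.items())
                )
                rules.append(Rule(conds))
            return
        name = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        left = dict(bounds)
        key = (name, "<=")
        left[key] = min(left.get(key, np.inf), thr)
        descend(t.children_left[node], left)
        right = dict(bounds)
        key = (name, ">")
        right[key] = max(right.get(key, -np.inf), thr)
        descend(t.children_right[node], right)

    descend(0, {})
    return rules


def induce_rules(positives, negatives, params: RuleLearnerParams | None = None,
                 seed=0, descriptor_names=None) -> RuleEnsemble:
    """Learn an ensemble of conjunctive rules separating originals from
    randomized copies.

    Each of ``n_trees`` bagged, depth-limited decision trees is fitted on
    a bootstrap resample of the combined task; every root-to-leaf path
    ending in a positive-enriched leaf is emitted as one rule.  The
    returned ensemble is reproducible under ``seed``.  A degenerate task
    (positives indistinguishable from negatives) produces a warning, not
    an error.
    """
    params = params or RuleLearnerParams()
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.shape[0] < 2:
        raise ConfigurationError("need at least two positive instances")
    if neg.shape[0] < 1:
        raise ConfigurationError("need at least one negative instance")
    if pos.shape[1] != neg.shape[1]:
        raise ConfigurationError("positives and negatives differ in width")
    names = list(descriptor_names) if descriptor_names is not None else [
        f"f{j}" for j in range(pos.shape[1])]

    if pos.shape == neg.shape and np.array_equal(pos, neg):
        warnings.warn("degenerate similarity task: positives equal negatives",
                      stacklevel=2)

    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(pos.shape[0], dtype=int),
                        np.zeros(neg.shape[0], dtype=int)])
    rng = np.random.default_rng(seed)
    n = X.shape[0]

    rules: list[Rule] = []
    for _ in range(params.n_trees):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:  # resample lost a class; redraw once
            idx = rng.permutation(n)
        tree = DecisionTreeClassifier(
            max_depth=params.max_depth,
            max_features=params.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        rules.extend(_paths_from_tree(tree, names, strict=True))

    if not rules:
        warnings.warn("no strictly positive-enriched leaves; relaxing the "
                      "emission criterion to ties", stacklevel=2)
        rng = np.random.default_rng(seed)
        for _ in range(params.n_trees):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) < 2:
                idx = rng.permutation(n)
            tree = DecisionTreeClassifier(
                max_depth=params.max_depth,
                max_features=params.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            rules.extend(_paths_from_tree(tree, names, strict=False))
    if not rules:
        raise ConfigurationError("rule induction produced no rules")

    provenance = {
        "n_trees": params.n_trees,
        "max_depth": params.max_depth,
        "max_features": str(params.max_features),
        "seed": int(seed),
        "n_positives": int(pos.shape[0]),
        "n_negatives": int(neg.shape[0]),
    }
    return RuleEnsemble(rules=rules, provenance=provenance)


def est_from_ensemble(ensemble: RuleEnsemble, frame: pd.DataFrame,
                      layer_id: str = "") -> SimilarityTable:
    """EST for a fixed rule ensemble: ``x_ij`` is the fraction of rules
    covering both instances, ``x_ii = 1``."""
    cov = np.stack([r.covers_matrix(frame) for r in ensemble.rules])  # R x N
    counts = cov.astype(np.float64).T @ cov.astype(np.float64)
    x = counts / float(ensemble.R)
    np.fill_diagonal(x, 1.0)
    x = np.clip(x, 0.0, 1.0)
    return SimilarityTable(x=x, subjects=[str(s) for s in frame.index],
                           layer_id=layer_id)


def compute_est(layer, params: RuleLearnerParams | None = None,
                seed=0) -> SimilarityTable:
    """Compute the EST of one (imputed) data layer.

    Internally draws ``m`` randomized negatives (``m = N`` by default),
    induces the rule ensemble, and counts shared coverage over the
    original instances.  Deterministic under ``seed``.
    """
    params = params or RuleLearnerParams()
    frame = layer.data if hasattr(layer, "data") else pd.DataFrame(np.asarray(layer))
    matrix = frame.to_numpy(dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise ConfigurationError("need at least two instances for an EST")
    if n > 1000:
        warnings.warn("similarity tables beyond 1000 instances are untested "
                      "territory for this method", stacklevel=2)
    if np.isnan(matrix).any():
        raise ConfigurationError("layer must be imputed before computing an EST")

    ss = np.random.SeedSequence(seed)
    seed_neg, seed_rules = [int(s.generate_state(1)[0] % (2**31 - 1))
                            for s in ss.spawn(2)]
    m = params.n_negatives or n
    negatives = randomize_instances(matrix, m, seed_neg)
    ensemble = induce_rules(matrix, negatives, params, seed_rules,
                            descriptor_names=list(frame.columns))
    layer_id = getattr(layer, "layer_id", "")
    return est_from_ensemble(ensemble, frame, layer_id=layer_id)
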