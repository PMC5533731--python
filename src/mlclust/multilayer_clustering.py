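"""Agglomerative multilayer clustering by clustering-related variability.

The objective is built on the similarity table of each layer.  For an
instance ``i`` in cluster ``C``, the clustering-related variability

    CRV_i = CRV_i,wc + CRV_i,oc

is the sum of squared deviations of the row-``i`` similarities around
their mean, taken separately over the columns inside ``C`` (within) and
outside ``C``.  A good cluster makes both parts small: its members'
similarities to co-members are uniformly high and to outsiders uniformly
low.  ``CRV_C`` sums ``CRV_i`` over the members of ``C``, and

    DIFF_xy = CRV_x + CRV_y - CRV_{x u y}

is the reduction achieved by merging clusters ``x`` and ``y``.  Starting
from singletons, the pair with the maximal DIFF is merged while that
maximum is strictly positive.  With several layers a merge must pay off
in every layer: the joint DIFF is the minimum of the per-layer DIFFs.

Conventions: the diagonal ``x_ii = 1`` is excluded from every sum, an
empty index set contributes 0, and a singleton cluster has zero
within-cluster variability.  Ties between equally good merges are broken
toward the lexicographically smallest (min id, max id) pair for
determinism.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .rule_similarity import SimilarityTable

__all__ = [
    "Partition", "CRVBreakdown", "MergeStep", "MergeTrace", "Clustering",
    "crv_instance", "crv_cluster", "diff_merge", "joint_diff", "cluster",
    "label_unclustered",
]

#: Final clusters smaller than this are flagged "unclustered" by default.
DEFAULT_MIN_CLUSTER_SIZE = 20


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

class Partition:
    """A partition of instance indices ``0..N-1`` into disjoint clusters
    with stable integer ids."""

    def __init__(self, clusters, n: int | None = None):
        if isinstance(clusters, Partition):
            self._clusters = dict(clusters._clusters)
        elif isinstance(clusters, dict):
            self._clusters = {int(k): frozenset(int(i) for i in v)
                              for k, v in clusters.items()}
        else:
            self._clusters = {k: frozenset(int(i) for i in members)
                              for k, members in enumerate(clusters)}
        members = [i for c in self._clusters.values() for i in c]
        if any(len(c) == 0 for c in self._clusters.values()):
            raise ConfigurationError("empty cluster in partition")
        if len(members) != len(set(members)):
            raise ConfigurationError("overlapping clusters in partition")
        self.n = n if n is not None else (max(members) + 1 if members else 0)
        if set(members) != set(range(self.n)):
            raise ConfigurationError("partition must cover 0..N-1 exactly")

    @classmethod
    def singletons(cls, n: int) -> "Partition":
        return cls({i: (i,) for i in range(n)}, n=n)

    @property
    def clusters(self) -> dict[int, frozenset]:
        return dict(self._clusters)

    def members(self, cluster_id: int) -> frozenset:
        if cluster_id not in self._clusters:
            raise ConfigurationError(f"unknown cluster id {cluster_id}")
        return self._clusters[cluster_id]

    def cluster_of(self, i: int) -> int:
        for cid, members in self._clusters.items():
            if i in members:
                return cid
        raise ConfigurationError(f"instance index {i} out of range")

    def merged(self, a: int, b: int, new_id: int | None = None) -> "Partition":
        if a == b:
            raise ConfigurationError("cannot merge a cluster with itself")
        ma, mb = self.members(a), self.members(b)
        out = {k: v for k, v in self._clusters.items() if k not in (a, b)}
        out[new_id if new_id is not None else min(a, b)] = ma | mb
        return Partition(out, n=self.n)

    def __len__(self):
        return len(self._clusters)

    def __iter__(self):
        return iter(self._clusters.items())


def _as_partition(partition) -> Partition:
    return partition if isinstance(partition, Partition) else Partition(partition)


def _as_matrix(est) -> np.ndarray:
    x = est.x if isinstance(est, SimilarityTable) else np.asarray(est, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ConfigurationError("similarity table must be square")
    return x


def _ss(values: np.ndarray) -> float:
    """Sum of squared deviations around the mean; 0 for empty input."""
    if values.size == 0:
        return 0.0
    return float(np.sum((values - values.mean()) ** 2))


# ---------------------------------------------------------------------------
# Reference CRV / DIFF (direct from the definitions)
# ---------------------------------------------------------------------------

@dataclass
class CRVBreakdown:
    """Per-instance within/outside variabilities under one partition."""

    wc: np.ndarray
    oc: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.wc + self.oc


def crv_instance(est, partition, i: int) -> tuple[float, float]:
    """The pair (CRV_i,wc, CRV_i,oc) of instance ``i``.

    Within-cluster variability is the squared deviation of row ``i``'s
    similarities to its co-members around their mean (0 for a singleton);
    outside-cluster variability is the same over all non-members.  The
    diagonal entry never participates.
    """
    x = _as_matrix(est)
    p = _as_partition(partition)
    n = x.shape[0]
    if not 0 <= i < n:
        raise ConfigurationError(f"instance index {i} out of range")
    members = p.members(p.cluster_of(i))
    inside = np.array(sorted(members - {i}), dtype=int)
    outside = np.array(sorted(set(range(n)) - members), dtype=int)
    return _ss(x[i, inside]), _ss(x[i, outside])


def crv_breakdown(est, partition) -> CRVBreakdown:
    x = _as_matrix(est)
    n = x.shape[0]
    wc = np.empty(n)
    oc = np.empty(n)
    for i in range(n):
        wc[i], oc[i] = crv_instance(est, partition, i)
    return CRVBreakdown(wc=wc, oc=oc)


def crv_cluster(est, partition, cluster) -> float:
    """CRV of a cluster: the sum of CRV_i over its members."""
    p = _as_partition(partition)
    members = p.members(cluster) if isinstance(cluster, int) else frozenset(cluster)
    total = 0.0
    for i in sorted(members):
        wc, oc = crv_instance(est, p, i)
        total += wc + oc
    return total


def diff_merge(est, partition, a: int, b: int) -> float:
    """CRV reduction from merging clusters ``a`` and ``b``:
    ``CRV_a + CRV_b - CRV_{a u b}`` with the union evaluated in the
    partition where only ``a`` and ``b`` changed."""
    p = _as_partition(partition)
    if a == b:
        raise ConfigurationError("cannot merge a cluster with itself")
    before = crv_cluster(est, p, a) + crv_cluster(est, p, b)
    merged = p.merged(a, b)
    new_id = min(a, b)
    after = crv_cluster(est, merged, new_id)
    return before - after


def joint_diff(ests, partition, a: int, b: int) -> float:
    """The min rule across layers: a merge must pay off in every layer."""
    mats = [_as_matrix(e) for e in ests]
    if len(mats) == 0:
        raise ConfigurationError("need at least one layer")
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ConfigurationError("layers disagree on the number of instances")
    return min(diff_merge(m, partition, a, b) for m in mats)


# ---------------------------------------------------------------------------
# Fast agglomeration
# ---------------------------------------------------------------------------

@dataclass
class MergeStep:
    """One executed merge: cluster ids, their members, per-layer DIFFs and
    the joint DIFF that triggered the merge."""

    a: int
    b: int
    new_id: int
    members_a: tuple[int, ...]
    members_b: tuple[int, ...]
    per_layer_diff: tuple[float, ...]
    joint: float


@dataclass
class MergeTrace:
    """The full history of one clustering run."""

    n: int
    n_layers: int
    steps: list[MergeStep]
    final: list[tuple[int, ...]]          # member tuples, sorted
    best_remaining_joint: float | None    # None when fully merged
    subjects: list[str] | None = None

    def final_partition(self) -> Partition:
        return Partition([set(c) for c in self.final], n=self.n)

    def to_json(self, path) -> None:
        doc = {
            "n": self.n,
            "n_layers": self.n_layers,
            "best_remaining_joint": self.best_remaining_joint,
            "subjects": self.subjects,
            "steps": [
                {"a": s.a, "b": s.b, "new_id": s.new_id,
                 "members_a": list(s.members_a), "members_b": list(s.members_b),
                 "per_layer_diff": list(s.per_layer_diff), "joint": s.joint}
                for s in self.steps
            ],
            "final": [list(c) for c in self.final],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


class _LayerState:
    """Aggregated row sums per cluster for O(|a|+|b|) DIFF evaluation.

    For each cluster ``c`` we keep ``S[c][i] = sum_{j in c} x_ij`` and the
    analogous sum of squares; diagonal terms are subtracted analytically
    (``x_ii = 1`` by convention).  Within/outside sums of squared
    deviations follow from ``q - s^2 / n``.
    """

    def __init__(self, x: np.ndarray):
        self.x = x
        self.n = x.shape[0]
        self.diag = np.diag(x).copy()
        self.row_s = x.sum(axis=1) - self.diag
        self.row_q = (x * x).sum(axis=1) - self.diag ** 2
        self.S: dict[int, np.ndarray] = {}
        self.Q: dict[int, np.ndarray] = {}
        for i in range(self.n):
            self.S[i] = x[:, i].copy()
            self.Q[i] = x[:, i] ** 2

    def _crv_sum(self, members: np.ndarray, s_in: np.ndarray, q_in: np.ndarray,
                 size: int) -> float:
        d = self.diag[members]
        s = s_in - d
        q = q_in - d ** 2
        nw = size - 1
        wc = np.maximum(q - s * s / nw, 0.0) if nw > 0 else 0.0
        no = self.n - size
        if no > 0:
            so = self.row_s[members] - s
            qo = self.row_q[members] - q
            oc = np.maximum(qo - so * so / no, 0.0)
        else:
            oc = 0.0
        return float(np.sum(wc + oc))

    def pair_diff(self, ma: np.ndarray, mb: np.ndarray, a: int, b: int) -> float:
        before = (self._crv_sum(ma, self.S[a][ma], self.Q[a][ma], ma.size)
                  + self._crv_sum(mb, self.S[b][mb], self.Q[b][mb], mb.size))
        m = np.concatenate([ma, mb])
        s_un = self.S[a][m] + self.S[b][m]
        q_un = self.Q[a][m] + self.Q[b][m]
        after = self._crv_sum(m, s_un, q_un, m.size)
        return before - after

    def singleton_diff_matrix(self) -> np.ndarray:
        """DIFF for every singleton pair at once (closed form)."""
        x, n = self.x, self.n
        if n < 3:
            # degenerate sizes: fall back to the generic path
            out = np.full((n, n), -np.inf)
            for p in range(n):
                for q in range(p + 1, n):
                    out[p, q] = out[q, p] = self.pair_diff(
                        np.array([p]), np.array([q]), p, q)
            return out
        crv_s = self.row_q - self.row_s ** 2 / (n - 1)
        s_o = self.row_s[:, None] - x
        q_o = self.row_q[:, None] - x ** 2
        oc = q_o - s_o ** 2 / (n - 2)
        diff = crv_s[:, None] + crv_s[None, :] - oc - oc.T
        np.fill_diagonal(diff, -np.inf)
        return diff

    def merge(self, a: int, b: int, new_id: int) -> None:
        self.S[new_id] = self.S.pop(a) + self.S.pop(b)
        self.Q[new_id] = self.Q.pop(a) + self.Q.pop(b)


def cluster(ests) -> MergeTrace:
    """Run the agglomeration on one or more similarity tables.

    Starts from singletons and repeatedly merges the pair of clusters
    with the maximal joint DIFF while that maximum is strictly positive;
    otherwise the current solution is final.  Returns the full
    :class:`MergeTrace`.  Internally uses incremental aggregate updates;
    the result matches a full recomputation from the displayed formulas.
    """
    if not isinstance(ests, (list, tuple)):
        ests = [ests]
    if len(ests) == 0:
        raise ConfigurationError("need at least one layer")
    mats = [_as_matrix(e) for e in ests]
    n = mats[0].shape[0]
    if n < 2:
        raise ConfigurationError("need at least two instances")
    if any(m.shape[0] != n for m in mats):
        raise ConfigurationError("layers disagree on the number of instances")
    subjects = None
    for e in ests:
        if isinstance(e, SimilarityTable):
            subjects = list(e.subjects)
            break

    layers = [_LayerState(m) for m in mats]
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}

    # seed the heap with all singleton pairs, vectorised per layer
    per_layer0 = np.stack([st.singleton_diff_matrix() for st in layers])
    joint0 = per_layer0.min(axis=0)
    heap: list[tuple] = []
    pair_layers: dict[tuple[int, int], tuple[float, ...]] = {}
    for p in range(n):
        for q in range(p + 1, n):
            heap.append((-joint0[p, q], p, q))
            pair_layers[(p, q)] = tuple(float(per_layer0[l, p, q])
                                        for l in range(len(layers)))
    heapq.heapify(heap)

    steps: list[MergeStep] = []
    next_id = n
    best_remaining: float | None = None
    while len(members) > 1:
        # pop until a live pair surfaces
        while heap:
            neg_joint, a, b = heap[0]
            if a in members and b in members:
                break
            heapq.heappop(heap)
        if not heap:
            break
        neg_joint, a, b = heapq.heappop(heap)
        joint = -neg_joint
        if not joint > 0.0:
            best_remaining = joint
            break
        new_id = next_id
        next_id += 1
        steps.append(MergeStep(
            a=a, b=b, new_id=new_id,
            members_a=tuple(int(i) for i in members[a]),
            members_b=tuple(int(i) for i in members[b]),
            per_layer_diff=pair_layers[(a, b)],
            joint=float(joint),
        ))
        merged = np.sort(np.concatenate([members[a], members[b]]))
        for st in layers:
            st.merge(a, b, new_id)
        del members[a], members[b]
        members[new_id] = merged
        for other, mo in members.items():
            if other == new_id:
                continue
            per_layer = tuple(
                float(st.pair_diff(merged, mo, new_id, other)) for st in layers)
            key = (min(new_id, other), max(new_id, other))
            pair_layers[key] = per_layer
            heapq.heappush(heap, (-min(per_layer), key[0], key[1]))

    final = sorted(
        (tuple(int(i) for i in m) for m in members.values()),
        key=lambda c: (c[0],),
    )
    return MergeTrace(n=n, n_layers=len(layers), steps=steps, final=final,
                      best_remaining_joint=best_remaining, subjects=subjects)


# ---------------------------------------------------------------------------
# Final labelling
# ---------------------------------------------------------------------------

@dataclass
class Clustering:
    """Named final clusters plus the unclustered remainder.

    ``labels[i]`` is ``"C1"``, ``"C2"``, ... (clusters ranked by size,
    largest first) or ``"unclustered"``.
    """

    labels: list[str]
    subjects: list[str] | None = None
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE

    @property
    def named_clusters(self) -> list[str]:
        seen = sorted({l for l in self.labels if l != "unclustered"},
                      key=lambda l: int(l[1:]))
        return seen

    def size_of(self, label: str) -> int:
        return sum(1 for l in self.labels if l == label)

    def indices_of(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]

    def to_csv(self, path) -> None:
        import pandas as pd

        ids = self.subjects or [str(i) for i in range(len(self.labels))]
        pd.DataFrame({"subject_id": ids, "cluster": self.labels}).to_csv(
            path, index=False)


def label_unclustered(trace: MergeTrace,
                      min_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> Clustering:
    """Flag final clusters below ``min_size`` as unclustered and rank the
    rest by size (ties broken by the smallest member index)."""
    if min_size < 1:
        raise ConfigurationError("min_size must be >= 1")
    named = [c for c in trace.final if len(c) >= min_size]
    named.sort(key=lambda c: (-len(c), c[0]))
    labels = ["unclustered"] * trace.n
    for rank, members in enumerate(named, start=1):
        for i in members:
            labels[i] = f"C{rank}"
    return Clustering(labels=labels, subjects=trace.subjects, min_size=min_size)
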