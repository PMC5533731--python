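"""Cluster characterisation: group contrasts and diagnosis transitions.

Numeric descriptors are contrasted between two clusters with the
Mann-Whitney rank-sum test (tie-corrected normal approximation, exact
enumeration for small samples); the APOE4-positivity indicator uses an
uncorrected Pearson chi-square on the 2x2 table.  Diagnosis trajectories
are summarised per cluster as conversion (any visit with a dementia
diagnosis), reversion (any cognitively-normal visit and no dementia
visit) and stable counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, build_layers
from .errors import ConfigurationError, UndefinedStatistic
from .multilayer_clustering import Clustering

logger = logging.getLogger(__name__)

#: Exact Mann-Whitney enumeration is used up to this pooled sample size.
EXACT_ENUMERATION_LIMIT = 10


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample ``a`` versus ``b`` with the midrank tie convention."""
    u = 0.0
    for x in a:
        u += np.sum(x > b) + 0.5 * np.sum(x == b)
    return float(u)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney rank-sum test; returns ``(z, p)`` two-sided.

    Missing values are dropped.  The z statistic uses the tie-corrected
    normal approximation of U (no continuity correction).  When the
    pooled sample size is at most 10 the p-value comes from exact
    enumeration of all group assignments instead.  All values tied across
    both samples gives ``(0, 1)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 0.0, 1.0

    u = _u_statistic(a, b)
    mu = na * nb / 2.0

    n = na + nb
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if var <= 0 else (u - mu) / np.sqrt(var)
    del ranks

    if n <= EXACT_ENUMERATION_LIMIT:
        dev = abs(u - mu)
        count = 0
        total = 0
        idx = range(n)
        for comb in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= dev - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = 1.0 if var <= 0 else 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def chi_square_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 count table, df = 1.

    Uses the closed form ``n (ad - bc)^2 / (r1 r2 c1 c2)``.  A zero row
    or column margin leaves the statistic undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigurationError("need a 2x2 table of non-negative counts")
    n = t.sum()
    if n <= 0:
        raise ConfigurationError("table total must be positive")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise UndefinedStatistic("chi-square undefined for a zero margin")
    stat = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (r[0] * r[1] * c[0] * c[1])
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Cluster contrast tables
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    """One descriptor's contrast between two clusters."""

    descriptor: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test: str          # "mann-whitney" or "chi-square"
    statistic: float   # |z| or the chi-square value
    p: float
    p_bh: float | None = None


def _subject_values(cohort: CohortTable, descriptors) -> pd.DataFrame:
    """Raw (un-imputed) subject x descriptor values, baselines and slopes."""
    schema = cohort.schema
    base = [d for d in descriptors if d in set(schema.baseline_names)]
    slopes = [d for d in descriptors if d in set(schema.slope_names)]
    unknown = [d for d in descriptors if d not in set(base) | set(slopes)]
    for d in unknown:
        logger.warning("compare_clusters: skipping unknown descriptor %r", d)
    layer1, layer2 = build_layers(cohort, base or [schema.baseline_names[0]], slopes or [schema.slope_names[0]])
    frames = []
    if base:
        frames.append(layer1.data[base])
    if slopes:
        frames.append(layer2.data[slopes])
    return pd.concat(frames, axis=1) if frames else pd.DataFrame(index=cohort.subjects)


def compare_clusters(
    cohort: CohortTable,
    clustering: Clustering,
    descriptors=None,
    stratum: str | None = None,
    groups: tuple[str, str] | None = None,
    benjamini_hochberg: bool = False,
) -> list[ComparisonRow]:
    """Per-descriptor contrast between two named clusters.

    Means and SDs are computed on non-missing values per cluster.
    Numeric descriptors get a Mann-Whitney test (|z| reported, matching
    the unsigned z convention of the cluster contrast tables); the
    ``APOE4`` descriptor is dichotomised to carrier status and tested
    with chi-square.  ``stratum`` restricts the comparison to one sex
    (``"F"``/``"M"``).  ``groups`` picks the two cluster labels; the
    default is the two largest named clusters.
    """
    named = clustering.named_clusters
    if groups is None:
        if len(named) < 2:
            raise ConfigurationError("need at least two named clusters")
        groups = (named[0], named[1])
    ga, gb = groups
    descriptors = list(descriptors or cohort.schema.descriptor_names)
    values = _subject_values(cohort, descriptors)
    subjects = clustering.subjects or list(values.index)

    in_a = {subjects[i] for i in clustering.indices_of(ga)}
    in_b = {subjects[i] for i in clustering.indices_of(gb)}
    if stratum is not None:
        in_a = {s for s in in_a if cohort.sex.get(s) == stratum}
        in_b = {s for s in in_b if cohort.sex.get(s) == stratum}

    rows: list[ComparisonRow] = []
    for d in descriptors:
        if d not in values.columns:
            continue
        col = values[d]
        a = col[col.index.isin(in_a)].dropna().to_numpy()
        b = col[col.index.isin(in_b)].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            logger.warning("compare_clusters: descriptor %r empty in a cluster", d)
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        sd_a = float(a.std(ddof=1)) if a.size > 1 else 0.0
        sd_b = float(b.std(ddof=1)) if b.size > 1 else 0.0
        if d == "APOE4":
            table = [[np.sum(a > 0), np.sum(a == 0)],
                     [np.sum(b > 0), np.sum(b == 0)]]
            try:
                stat, p = chi_square_2x2(table)
            except UndefinedStatistic:
                continue
            rows.append(ComparisonRow(d, a.size, b.size, mean_a, sd_a,
                                      mean_b, sd_b, "chi-square", stat, p))
        else:
            if a.size < 2 or b.size < 2:
                rows.append(ComparisonRow(d, a.size, b.size, mean_a, sd_a,
                                          mean_b, sd_b, "mann-whitney",
                                          float("nan"), float("nan")))
                continue
            z, p = mann_whitney(a, b)
            rows.append(ComparisonRow(d, a.size, b.size, mean_a, sd_a,
                                      mean_b, sd_b, "mann-whitney", abs(z), p))

    if benjamini_hochberg and rows:
        ps = np.array([r.p for r in rows])
        order = np.argsort(ps)
        m = np.isfinite(ps).sum()
        adj = np.full_like(ps, np.nan)
        running = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            if not np.isfinite(ps[idx]):
                continue
            running = min(running, ps[idx] * m / rank)
            adj[idx] = running
        for r, q in zip(rows, adj):
            r.p_bh = None if not np.isfinite(q) else float(q)
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Rows as a tabular report mirroring the published contrast layout."""
    return pd.DataFrame(
        {
            "descriptor": [r.descriptor for r in rows],
            "n_a": [r.n_a for r in rows],
            "mean_a": [r.mean_a for r in rows],
            "sd_a": [r.sd_a for r in rows],
            "n_b": [r.n_b for r in rows],
            "mean_b": [r.mean_b for r in rows],
            "sd_b": [r.sd_b for r in rows],
            "test": [r.test for r in rows],
            "statistic": [r.statistic for r in rows],
            "p": [r.p for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Diagnosis transitions
# ---------------------------------------------------------------------------

@dataclass
class ClusterTransitions:
    n: int
    converted: int
    reverted: int
    stable: int

    @property
    def conversion_pct(self) -> float:
        return 100.0 * self.converted / self.n if self.n else float("nan")

    @property
    def reversion_pct(self) -> float:
        return 100.0 * self.reverted / self.n if self.n else float("nan")

    @property
    def stable_pct(self) -> float:
        return 100.0 * self.stable / self.n if self.n else float("nan")


@dataclass
class TransitionReport:
    """Per-cluster (plus overall) conversion/reversion/stable counts."""

    per_cluster: dict[str, ClusterTransitions]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": list(self.per_cluster),
                "n": [t.n for t in self.per_cluster.values()],
                "converted": [t.converted for t in self.per_cluster.values()],
                "reverted": [t.reverted for t in self.per_cluster.values()],
                "stable": [t.stable for t in self.per_cluster.values()],
                "conversion_pct": [t.conversion_pct for t in self.per_cluster.values()],
                "reversion_pct": [t.reversion_pct for t in self.per_cluster.values()],
            }
        )


def _subject_outcome(cohort: CohortTable, sid: str) -> str:
    """'converted' if any visit diagnosis is Dementia; 'reverted' if any
    is CN and none Dementia; otherwise 'stable'.  Dementia outranks CN
    for subjects showing both."""
    post = [v.diagnosis for v in cohort.visits[sid][1:] if v.diagnosis is not None]
    if not post:
        logger.info("transition_rates: subject %s has no post-baseline "
                    "diagnosis; counted stable", sid)
        return "stable"
    if "Dementia" in post:
        return "converted"
    if "CN" in post:
        return "reverted"
    return "stable"


def transition_rates(cohort: CohortTable, clustering: Clustering | None = None
                     ) -> TransitionReport:
    """Count diagnosis outcomes per cluster and overall."""
    subjects = (clustering.subjects if clustering and clustering.subjects
                else cohort.subjects)
    labels = (clustering.labels if clustering
              else ["overall"] * len(subjects))
    groups: dict[str, list[str]] = {}
    for sid, label in zip(subjects, labels):
        groups.setdefault(label, []).append(sid)
    groups["overall"] = list(subjects)

    per_cluster: dict[str, ClusterTransitions] = {}
    for label, members in groups.items():
        outcomes = [_subject_outcome(cohort, s) for s in members]
        per_cluster[label] = ClusterTransitions(
            n=len(members),
            converted=outcomes.count("converted"),
            reverted=outcomes.count("reverted"),
            stable=outcomes.count("stable"),
        )
    return TransitionReport(per_cluster=per_cluster)
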