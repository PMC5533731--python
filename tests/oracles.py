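"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the defining formulas, with no
shared code paths with the package, so agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# -- clustering-related variability -----------------------------------------

def crv_instance_brute(x: np.ndarray, clusters, i: int) -> tuple[float, float]:
    """(wc, oc) for instance i: sums of squared deviations of row-i
    similarities around their mean, inside and outside i's cluster,
    diagonal excluded."""
    n = x.shape[0]
    own = next(c for c in clusters if i in c)
    inside = [j for j in own if j != i]
    outside = [j for j in range(n) if j not in own]
    wc = float(np.sum((x[i, inside] - np.mean(x[i, inside])) ** 2)) if inside else 0.0
    oc = float(np.sum((x[i, outside] - np.mean(x[i, outside])) ** 2)) if outside else 0.0
    return wc, oc


def crv_cluster_brute(x: np.ndarray, clusters, members) -> float:
    return sum(sum(crv_instance_brute(x, clusters, i)) for i in members)


def diff_merge_brute(x: np.ndarray, clusters, a: int, b: int) -> float:
    before = (crv_cluster_brute(x, clusters, clusters[a])
              + crv_cluster_brute(x, clusters, clusters[b]))
    merged = [c for k, c in enumerate(clusters) if k not in (a, b)]
    merged.append(set(clusters[a]) | set(clusters[b]))
    after = crv_cluster_brute(x, merged, merged[-1])
    return before - after


# -- least squares -----------------------------------------------------------

def ols_slope_normal_equations(months, values) -> float:
    """Slope via the explicit normal equations (X'X)^-1 X'y."""
    t = np.asarray(months, dtype=float)
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1])


# -- rank statistics ---------------------------------------------------------

def mann_whitney_exact_p(a, b) -> float:
    """Two-sided p by full enumeration of all group assignments of the
    pooled values, using |U - mean| as the ordering statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size
    mu = na * b.size / 2.0

    def u_of(sample_a, sample_b):
        u = 0.0
        for v in sample_a:
            u += np.sum(v > sample_b) + 0.5 * np.sum(v == sample_b)
        return u

    dev = abs(u_of(a, b) - mu)
    hits = total = 0
    for comb in combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        if abs(u_of(pooled[mask], pooled[~mask]) - mu) >= dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman_rank_then_pearson(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def chi2_closed_form(table) -> float:
    t = np.asarray(table, dtype=float)
    n = t.sum()
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    return float(n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2
                 / (r[0] * r[1] * c[0] * c[1]))


# -- threshold search --------------------------------------------------------

def best_univariate_brute(values, y, direction=">"):
    """Exhaustive scan over all midpoint thresholds; returns
    (threshold, J, sens, spec) with ties broken toward higher
    specificity, then the lower threshold."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    distinct = np.unique(v)
    cands = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for t in cands:
        fires = v > t if direction == ">" else v < t
        sens = np.sum(fires & y) / y.sum()
        spec = np.sum(~fires & ~y) / (~y).sum()
        key = (-(sens + spec - 1.0), -spec, t)
        if best is None or key < best[0]:
            best = (key, t, sens + spec - 1.0, sens, spec)
    return best[1], best[2], best[3], best[4]


def best_conjunction_brute(v1, v2, y):
    """Exhaustive double loop over both candidate-threshold grids."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    y = np.asarray(y, dtype=bool)
    d1 = np.unique(v1)
    d2 = np.unique(v2)
    c1 = (d1[:-1] + d1[1:]) / 2.0
    c2 = (d2[:-1] + d2[1:]) / 2.0
    best = None
    for t1 in c1:
        for t2 in c2:
            fires = (v1 > t1) & (v2 > t2)
            sens = np.sum(fires & y) / y.sum()
            spec = np.sum(~fires & ~y) / (~y).sum()
            key = (-(sens + spec - 1.0), -spec, t1, t2)
            if best is None or key < best[0]:
                best = (key, t1, t2, sens + spec - 1.0)
    return best[1], best[2], best[3]
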