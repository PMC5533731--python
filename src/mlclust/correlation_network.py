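"""Descriptor correlation networks.

Pairwise Spearman rank correlations over all descriptors (baseline
values and longitudinal slopes, pairwise-complete on missing data) are
thresholded into an undirected graph whose edge length is the inverse
correlation, ``dist = 1 / |rho|`` — small distance means strong
association.  The graph is exported in GraphML for downstream
force-directed layout; isolated nodes are kept, since unconnected
descriptors are themselves informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import DescriptorSchema
from .errors import ConfigurationError

#: Default correlation threshold for retaining an edge.
DEFAULT_RHO_THRESHOLD = 0.5

#: Fewest complete pairs for a defined correlation.
MIN_COMPLETE_PAIRS = 3


@dataclass
class CorrelationEdge:
    node_a: str
    node_b: str
    rho: float
    n_pairs: int

    @property
    def dist(self) -> float:
        return 1.0 / abs(self.rho)


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: list[CorrelationEdge]
    node_attrs: dict[str, dict] = field(default_factory=dict)


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Tie-corrected Spearman rho for every descriptor pair,
    pairwise-complete; entries with fewer than three complete pairs (and
    constant columns) are left undefined (NaN)."""
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    if data.shape[1] < 1:
        raise ConfigurationError("need at least one descriptor")
    rho = data.corr(method="spearman", min_periods=MIN_COMPLETE_PAIRS)
    np.fill_diagonal(rho.values, 1.0)
    return rho


def complete_pair_counts(data: pd.DataFrame) -> pd.DataFrame:
    present = data.notna().astype(int)
    counts = present.T @ present
    return counts


def build_network(
    rho_matrix: pd.DataFrame,
    threshold: float = DEFAULT_RHO_THRESHOLD,
    n_pairs: pd.DataFrame | None = None,
) -> CorrelationNetwork:
    """Retain an edge wherever ``|rho| >= threshold`` (inclusive; the
    absolute value keeps strongly anti-correlated scales, e.g. a
    cognitive score and an error count, linked).  All nodes are retained
    whether or not they gain an edge."""
    nodes = [str(c) for c in rho_matrix.columns]
    edges: list[CorrelationEdge] = []
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            b = nodes[j]
            rho = rho_matrix.iloc[i, j]
            if pd.isna(rho) or abs(rho) < threshold:
                continue
            count = int(n_pairs.iloc[i, j]) if n_pairs is not None else 0
            edges.append(CorrelationEdge(a, b, float(rho), count))
    return CorrelationNetwork(nodes=nodes, edges=edges)


def annotate_nodes(network: CorrelationNetwork,
                   schema: DescriptorSchema | None = None) -> None:
    """Attach role (baseline vs slope) and category attributes in place."""
    for name in network.nodes:
        attrs = network.node_attrs.setdefault(name, {})
        attrs["role"] = "slope" if name.startswith("S") and (
            schema is None or name not in {d.name for d in schema.baseline}
        ) else "baseline"
        if schema is not None:
            try:
                attrs["category"] = schema.category_of(name)
            except ConfigurationError:
                attrs["category"] = "unknown"


def to_graph(network: CorrelationNetwork) -> nx.Graph:
    g = nx.Graph()
    for name in network.nodes:
        g.add_node(name, **network.node_attrs.get(name, {}))
    for e in network.edges:
        g.add_edge(e.node_a, e.node_b, rho=e.rho, dist=e.dist, weight=abs(e.rho),
                   n_pairs=e.n_pairs)
    return g


def export_graph(network: CorrelationNetwork, path,
                 schema: DescriptorSchema | None = None) -> None:
    """Write the network as GraphML with node role/category attributes
    and edge weights; the force-directed layout itself is downstream."""
    annotate_nodes(network, schema)
    nx.write_graphml(to_graph(network), path)


def export_edge_list(network: CorrelationNetwork, path) -> None:
    pd.DataFrame(
        {
            "node_a": [e.node_a for e in network.edges],
            "node_b": [e.node_b for e in network.edges],
            "rho": [e.rho for e in network.edges],
            "dist": [e.dist for e in network.edges],
            "n_pairs": [e.n_pairs for e in network.edges],
        }
    ).to_csv(path, index=False)
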