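"""Node-level network descriptors: centrality indices and predictability.

Centralities follow standard weighted-graph practice for partial-correlation
networks: strength is the sum of absolute edge weights; closeness and
betweenness use shortest paths on the distance transform d = 1/|w|, so
stronger edges are shorter.  Each index is also reported as a z-score across
nodes.  Node predictability is the share of a node's variance explained by
its neighbours — for a Gaussian model on the correlation scale this is
1 − 1/θ_jj with θ the (regularised) precision matrix, which at λ = 0 equals
the R² of regressing the standardised node on all others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import PartialCorrelationNetwork

__all__ = [
    "CentralityTable",
    "PredictabilityTable",
    "centrality_indices",
    "node_predictability",
    "node_predictability_unregularised",
    "predictability_summary",
]

_INDICES = ("strength", "closeness", "betweenness")


@dataclass
class CentralityTable:
    values: pd.DataFrame  # node × (strength, closeness, betweenness)
    zscores: pd.DataFrame  # same layout, z-standardised across nodes
    index_correlations: pd.DataFrame  # 3 × 3 Pearson correlations
    component_sizes: pd.Series  # size of each node's connected component


@dataclass
class PredictabilityTable:
    values: pd.Series  # per-node predictability in [0, 1]
    mean: float


def _distance_graph(net: PartialCorrelationNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.labels)
    p = net.p
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0:
                G.add_edge(net.labels[i], net.labels[j], distance=1.0 / abs(w))
    return G


def centrality_indices(net: PartialCorrelationNetwork) -> CentralityTable:
    """Strength, closeness and betweenness per node, raw and z-standardised.

    Closeness is 1 / (sum of shortest-path distances to the other nodes of
    the node's connected component); cross-component pairs are excluded
    rather than set to infinity, and component sizes are reported alongside.
    Betweenness is the standard weighted count of shortest paths through the
    node (unnormalised).  Empty networks yield all-zero centralities with a
    warning.
    """
    if net.p < 2:
        raise ValueError("centrality needs at least 2 nodes")
    G = _distance_graph(net)
    if G.number_of_edges() == 0:
        warnings.warn("empty network: all centralities are zero")
    strength = pd.Series(np.abs(net.weights).sum(axis=1), index=net.labels, name="strength")

    closeness = pd.Series(0.0, index=net.labels, name="closeness")
    comp_size = pd.Series(1, index=net.labels, name="component_size")
    for comp in nx.connected_components(G):
        nodes = list(comp)
        for v in nodes:
            comp_size[v] = len(nodes)
            if len(nodes) > 1:
                dists = nx.single_source_dijkstra_path_length(G, v, weight="distance")
                closeness[v] = 1.0 / sum(d for u, d in dists.items() if u != v)

    btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    betweenness = pd.Series(btw, name="betweenness").reindex(net.labels)

    values = pd.concat([strength, closeness, betweenness], axis=1)

    def zscore(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        return (col - col.mean()) / sd if sd > 0 else col * 0.0

    zs = values.apply(zscore)
    corr = values.corr(method="pearson")
    return CentralityTable(
        values=values, zscores=zs, index_correlations=corr, component_sizes=comp_size
    )


def node_predictability(net: PartialCorrelationNetwork, S=None) -> PredictabilityTable:
    """Per-node predictability 1 − 1/θ_jj from the selected precision matrix.

    The precision is on the correlation scale (the glasso was fit to a
    correlation matrix), so θ_jj ≥ 1 and the value lies in [0, 1]; isolated
    nodes get 0.  ``S`` is only used to cross-check labels when given.
    """
    if S is not None:
        labels = getattr(S, "labels", None)
        if labels is not None and list(labels) != list(net.labels):
            raise ValueError("network and correlation matrix labels differ")
    theta_diag = np.diag(net.precision)
    vals = np.clip(1.0 - 1.0 / theta_diag, 0.0, 1.0)
    series = pd.Series(vals, index=net.labels, name="predictability")
    return PredictabilityTable(values=series, mean=float(series.mean()))


def node_predictability_unregularised(S) -> PredictabilityTable:
    """Cross-check variant: R² of each standardised variable on all others.

    Computed from the inverse correlation matrix (1 − 1/(S⁻¹)_jj), i.e. the
    λ = 0 limit of :func:`node_predictability`.
    """
    Smat = S.values if hasattr(S, "values") and not isinstance(S, np.ndarray) else np.asarray(S)
    labels = getattr(S, "labels", [f"V{i+1}" for i in range(Smat.shape[0])])
    theta = np.linalg.inv(Smat)
    vals = np.clip(1.0 - 1.0 / np.diag(theta), 0.0, 1.0)
    series = pd.Series(vals, index=list(labels), name="predictability")
    return PredictabilityTable(values=series, mean=float(series.mean()))


def predictability_summary(table: PredictabilityTable | pd.Series) -> float:
    """Network-level mean predictability, rounded to 2 decimals for reporting."""
    values = table.values if isinstance(table, PredictabilityTable) else table
    if len(values) == 0:
        raise ValueError("empty predictability table")
    return float(round(np.mean(np.asarray(values, dtype=float)), 2))
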