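"""Centrality indices on the estimated weighted network.

Conventions follow the network-psychometrics workflow: edge "length" is the
reciprocal absolute weight 1/|w| (strong associations are short), so all
three indices are sign-blind.

* strength: Σ_j |w_ij| — total involvement of a node.
* closeness: 1 / Σ_j d(i, j) over the shortest-path distances to the
  *reachable* nodes only; an isolated node scores 0.
* betweenness: fraction of all-pairs shortest paths passing through the
  node (endpoints excluded, ties credited fractionally), normalized by the
  (p−1)(p−2)/2 pairs not involving it.

For reporting, each index is additionally min–max scaled to [0, 1] so that
1 marks the most and 0 the least central node.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import PartialCorrelationNetwork

__all__ = [
    "edge_distances",
    "strength",
    "closeness",
    "betweenness",
    "scale_minmax",
    "centrality_table",
]


def edge_distances(net: PartialCorrelationNetwork) -> np.ndarray:
    """Distance matrix d_ij = 1/|w_ij|, ∞ for non-edges, 0 on the diagonal."""
    w = np.abs(net.weights)
    with np.errstate(divide="ignore"):
        d = 1.0 / w
    np.fill_diagonal(d, 0.0)
    return d


def _graph(net: PartialCorrelationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    for a, b, w, _ in net.edges():
        g.add_edge(a, b, distance=1.0 / abs(w))
    return g


def strength(net: PartialCorrelationNetwork) -> np.ndarray:
    return np.abs(net.weights).sum(axis=1)


def closeness(net: PartialCorrelationNetwork) -> np.ndarray:
    g = _graph(net)
    out = np.zeros(net.p)
    for i, node in enumerate(net.labels):
        dists = nx.single_source_dijkstra_path_length(g, node, weight="distance")
        total = sum(d for other, d in dists.items() if other != node)
        out[i] = 1.0 / total if total > 0 else 0.0
    return out


def betweenness(net: PartialCorrelationNetwork) -> np.ndarray:
    g = _graph(net)
    bc = nx.betweenness_centrality(g, weight="distance", normalized=True)
    return np.array([bc[node] for node in net.labels])


def scale_minmax(values: np.ndarray) -> np.ndarray:
    """(v − min)/(max − min); an all-equal vector maps to zeros by convention."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("min–max scaling needs at least 2 nodes")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def centrality_table(net: PartialCorrelationNetwork) -> pd.DataFrame:
    """Raw and min–max scaled strength/closeness/betweenness per node."""
    s, c, b = strength(net), closeness(net), betweenness(net)
    return pd.DataFrame(
        {
            "strength": s,
            "closeness": c,
            "betweenness": b,
            "strength_scaled": scale_minmax(s),
            "closeness_scaled": scale_minmax(c),
            "betweenness_scaled": scale_minmax(b),
        },
        index=pd.Index(net.labels, name="node"),
    )
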