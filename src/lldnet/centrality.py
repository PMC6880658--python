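"""Centrality indices on the weighted symptom network.

Strength is the sum of absolute incident edge weights (direct
connectivity).  Closeness and betweenness operate on shortest paths with
edge length 1/|weight| — the usual convention for signed association
networks, where a stronger association means a shorter distance.
Closeness is the inverse of the summed distance to all reachable nodes
(0 for isolated nodes); betweenness credits a node with the fraction of
shortest paths between each pair of other nodes that pass through it,
splitting credit across ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import SymptomNetwork


@dataclass
class CentralityTable:
    labels: list
    strength: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.labels,
            "strength": self.strength,
            "closeness": self.closeness,
            "betweenness": self.betweenness,
        })


def strength(net: SymptomNetwork) -> np.ndarray:
    """s_i = sum_j |w_ij|."""
    return np.abs(net.weights).sum(axis=1)


def _length_graph(net: SymptomNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.p))
    iu, ju = np.triu_indices(net.p, 1)
    for i, j in zip(iu, ju):
        w = net.weights[i, j]
        if w != 0:
            g.add_edge(int(i), int(j), length=1.0 / abs(w))
    return g


def distance_centralities(net: SymptomNetwork):
    """(closeness, betweenness) per node on 1/|w| edge lengths."""
    g = _length_graph(net)
    p = net.p
    closeness = np.zeros(p)
    for i in range(p):
        dists = nx.single_source_dijkstra_path_length(g, i, weight="length")
        total = sum(d for node, d in dists.items() if node != i)
        closeness[i] = 1.0 / total if total > 0 else 0.0
    btw = nx.betweenness_centrality(g, weight="length", normalized=False)
    betweenness = np.array([btw[i] for i in range(p)])
    return closeness, betweenness


def centrality_table(net: SymptomNetwork) -> CentralityTable:
    clo, btw = distance_centralities(net)
    return CentralityTable(labels=list(net.labels), strength=strength(net),
                           closeness=clo, betweenness=btw)
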