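"""Per-node topological metrics and per-degree mean profiles.

For each node of a simple undirected graph we compute degree k, clustering
coefficient C = 2T / (k (k-1)) (0 when k < 2), neighborhood connectivity C_N
(mean neighbor degree), betweenness centrality C_B normalized by
(n-1)(n-2)/2, closeness C_C = (n_comp - 1) / sum of within-component
distances (0 for singletons), and eigenvector centrality C_E of the node's
connected component, rescaled so the maximum entry is 1.

The per-degree profile averages each metric over nodes of equal degree and
adds P(k), the fraction of nodes with degree k; these profiles are what the
power-law fits consume.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["node_metrics", "degree_profile", "eigenvector_centrality"]

METRIC_COLUMNS = ["k", "C", "C_N", "C_B", "C_C", "C_E"]


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("graph must be simple and undirected")
    if any(True for _ in nx.selfloop_edges(graph)):
        raise ValueError("graph must be simple: self-loops present")


def eigenvector_centrality(graph: nx.Graph) -> dict:
    """Eigenvector centrality per connected component, max entry scaled to 1.

    Uses the leading eigenpair of each component's dense adjacency matrix
    (symmetric eigendecomposition); by Perron-Frobenius the leading vector of
    a connected component is sign-constant, so entries are clipped to be
    non-negative before rescaling.  Singleton components get 1.0.
    """
    out: dict = {}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1:
            out[nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(graph, nodelist=nodes)
        w, v = np.linalg.eigh(a)
        vec = v[:, -1]
        if vec.sum() < 0:
            vec = -vec
        vec = np.clip(vec, 0.0, None)
        vec = vec / vec.max()
        out.update(zip(nodes, vec.tolist()))
    return out


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """All six per-node metrics as a DataFrame indexed by node symbol."""
    _check_simple(graph)
    nodes = sorted(graph.nodes, key=str)
    k = dict(graph.degree())
    clustering = nx.clustering(graph)
    neigh = nx.average_neighbor_degree(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    eigen = eigenvector_centrality(graph)
    df = pd.DataFrame(
        {
            "k": [k[n] for n in nodes],
            "C": [clustering[n] for n in nodes],
            "C_N": [neigh[n] for n in nodes],
            "C_B": [betweenness[n] for n in nodes],
            "C_C": [closeness[n] for n in nodes],
            "C_E": [eigen[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return df


def degree_profile(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-degree means of the five metrics plus P(k).

    One row per observed degree; degrees with no nodes are absent.
    Sum of P over rows is 1.
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    grouped = metrics.groupby("k")[["C", "C_N", "C_B", "C_C", "C_E"]].mean()
    counts = metrics.groupby("k").size()
    profile = grouped.copy()
    profile.insert(0, "P", counts / len(metrics))
    profile.index.name = "k"
    return profile


def write_metrics_tsv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index_label="node")


def read_metrics_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="node")
    df.index = df.index.astype(str)  # node symbols are strings in the graphs
    return df


def write_profile_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index_label="k")


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="k")
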