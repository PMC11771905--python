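"""Interaction-network construction from scored gene-gene interaction tables.

Reads STRING-style exports (integer combined scores on a 0-1000 scale) or
plain TSV edge lists with scores already in [0, 1], restricts edges to a gene
whitelist (typically the DEG symbols), and keeps edges whose combined score is
strictly above the confidence threshold (default 0.4, the STRING
medium-confidence cutoff).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_interactions",
    "interactions_from_frame",
    "build_network",
    "connected_components",
    "write_network_tsv",
    "read_network_tsv",
]

_STRING_COLS = ("protein1", "protein2", "combined_score")
_PLAIN_COLS = ("protein_a", "protein_b", "combined_score")


def interactions_from_frame(df: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Clean a raw (a, b, score) frame: drop self-pairs, collapse duplicate
    A-B/B-A rows keeping the maximum score, validate the [0, 1] range."""
    df = df.copy()
    df.columns = ["protein_a", "protein_b", "combined_score"]
    df["protein_a"] = df["protein_a"].astype(str)
    df["protein_b"] = df["protein_b"].astype(str)
    df["combined_score"] = df["combined_score"].astype(float) / scale

    selfpairs = df["protein_a"] == df["protein_b"]
    if selfpairs.any():
        logger.warning("dropping %d self-pair rows", int(selfpairs.sum()))
        df = df.loc[~selfpairs]

    bad = (df["combined_score"] < 0) | (df["combined_score"] > 1)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} scores outside [0, 1] after normalization"
        )

    # canonicalize unordered pairs, keep max score per pair
    a = df["protein_a"].to_numpy()
    b = df["protein_b"].to_numpy()
    swap = a > b
    lo = np.where(swap, b, a)
    hi = np.where(swap, a, b)
    df = pd.DataFrame(
        {"protein_a": lo, "protein_b": hi, "combined_score": df["combined_score"].values}
    )
    df = (
        df.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
        .max()
        .sort_values(["protein_a", "protein_b"])
        .reset_index(drop=True)
    )
    return df


def read_interactions(path, dialect: str = "string_tsv") -> pd.DataFrame:
    """Read an interaction table.

    ``string_tsv`` expects columns protein1/protein2/combined_score with
    integer scores on the 0-1000 scale (divided by 1000 here); ``plain_tsv``
    expects protein_a/protein_b/combined_score with scores already in [0, 1].
    """
    if dialect not in ("string_tsv", "plain_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    required = _STRING_COLS if dialect == "string_tsv" else _PLAIN_COLS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    df = df[list(required)]
    scale = 1000.0 if dialect == "string_tsv" else 1.0
    return interactions_from_frame(df, scale=scale)


def build_network(
    table: pd.DataFrame,
    node_whitelist,
    score_min: float = 0.4,
) -> nx.Graph:
    """Build the undirected interaction graph.

    Keeps edges with combined_score strictly greater than ``score_min`` and
    both endpoints in ``node_whitelist``; whitelist genes left isolated are
    excluded (their count is logged).  Raises if no edge survives.
    """
    whitelist = set(map(str, node_whitelist))
    if not whitelist:
        raise ValueError("empty node whitelist")
    keep = (
        (table["combined_score"] > score_min)
        & table["protein_a"].isin(whitelist)
        & table["protein_b"].isin(whitelist)
    )
    edges = table.loc[keep]
    if len(edges) == 0:
        raise ValueError("no edges above threshold")
    g = nx.Graph()
    for a, b, s in edges.itertuples(index=False):
        g.add_edge(a, b, score=float(s))
    n_isolated = len(whitelist) - g.number_of_nodes()
    logger.info(
        "network: %d nodes, %d edges (%d whitelist genes isolated or unmapped)",
        g.number_of_nodes(),
        g.number_of_edges(),
        n_isolated,
    )
    g.graph["n_isolated_whitelist"] = n_isolated
    return g


def connected_components(graph: nx.Graph) -> list[set]:
    """Maximal connected node sets, sorted by decreasing size (ties by the
    smallest member symbol, for determinism)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


def write_network_tsv(graph: nx.Graph, path) -> None:
    rows = [
        (min(a, b), max(a, b), data.get("score", 1.0))
        for a, b, data in graph.edges(data=True)
    ]
    df = pd.DataFrame(sorted(rows), columns=list(_PLAIN_COLS))
    df.to_csv(path, sep="\t", index=False)


def read_network_tsv(path) -> nx.Graph:
    table = read_interactions(path, dialect="plain_tsv")
    g = nx.Graph()
    for a, b, s in table.itertuples(index=False):
        g.add_edge(a, b, score=float(s))
    return g
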