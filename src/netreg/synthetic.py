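"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generator families stand in for the study's downloaded inputs so every
stage runs at desk scale:

* :func:`gen_expression` — a two-group log2-scale expression matrix with
  planted log2 fold changes (half up, half down) and gene-wise variance
  heterogeneity drawn from a scaled inverse-chi-square, the hierarchical
  model the empirical-Bayes screen assumes.
* :func:`gen_graph` — graphs with known ground truth: Barabasi-Albert
  preferential attachment (degree exponent ~ 3), a deterministic
  Ravasz-style hierarchical graph (C(k) ~ 1/k), planted-partition block
  graphs, and Erdos-Renyi nulls.  All emit scored interaction tables so
  they can flow through network construction.
* :func:`sample_powerlaw` — exact draws from continuous (Pareto) or
  discrete (Hurwitz-zeta) power laws, for fit-recovery tests.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CASE, CONTROL, ExpressionMatrix
from .powerlaw import power_law_tail_sampler

__all__ = ["gen_expression", "gen_graph", "graph_to_interactions", "sample_powerlaw"]


def gen_expression(
    n_genes: int = 2000,
    n_per_group: int = 10,
    n_deg: int = 100,
    effect_lfc: float = 2.0,
    baseline_range: tuple = (6.0, 12.0),
    sigma0: float = 0.4,
    d0: float = 10.0,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group matrix with planted effects.

    Control samples are Normal(baseline_g, sigma_g) per gene on the log2
    scale; for the first ``n_deg`` genes the case group is shifted by
    +effect_lfc (first half) or -effect_lfc (second half).  Gene-wise
    sigma_g^2 ~ d0 * sigma0^2 / chi2(d0), a scaled inverse-chi-square.

    Returns (matrix, truth) where truth has one row per gene with columns
    planted (bool), true_lfc.
    """
    if n_deg > n_genes:
        raise ValueError("n_deg must not exceed n_genes")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if effect_lfc < 0 or sigma0 <= 0 or d0 <= 0:
        raise ValueError("effect_lfc must be >= 0; sigma0, d0 must be > 0")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"ctrl_{j}" for j in range(n_per_group)] + [
        f"case_{j}" for j in range(n_per_group)
    ]
    groups = pd.Series(
        [CONTROL] * n_per_group + [CASE] * n_per_group, index=samples, dtype=object
    )

    baseline = rng.uniform(*baseline_range, size=n_genes)
    sigma2 = d0 * sigma0**2 / rng.chisquare(d0, size=n_genes)
    sigma = np.sqrt(sigma2)

    true_lfc = np.zeros(n_genes)
    n_up = (n_deg + 1) // 2
    true_lfc[:n_up] = effect_lfc
    true_lfc[n_up:n_deg] = -effect_lfc

    noise = rng.normal(size=(n_genes, 2 * n_per_group)) * sigma[:, None]
    values = baseline[:, None] + noise
    values[:, n_per_group:] += true_lfc[:, None]

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)
    truth = pd.DataFrame(
        {"planted": np.arange(n_genes) < n_deg, "true_lfc": true_lfc},
        index=pd.Index(genes, name="gene"),
    )
    return matrix, truth


def _hierarchical_graph(motif_size: int, levels: int) -> tuple[nx.Graph, dict]:
    """Deterministic Ravasz-style hierarchical graph.

    Level 1 is a ``motif_size``-clique with node 0 as hub.  Each further
    level replicates the current module ``motif_size - 1`` times and wires
    every peripheral node of the replicas to the central hub, giving
    motif_size**levels nodes and the characteristic C(k) ~ 1/k decay.
    """
    if motif_size < 3 or levels < 1:
        raise ValueError("need motif_size >= 3 and levels >= 1")
    g = nx.complete_graph(motif_size)
    hub = 0
    peripheral = list(range(1, motif_size))
    for _ in range(1, levels):
        n_cur = g.number_of_nodes()
        base_edges = list(g.edges)
        base_periph = list(peripheral)
        new_periph = []
        for rep in range(1, motif_size):
            off = rep * n_cur
            g.add_edges_from((u + off, v + off) for u, v in base_edges)
            rep_periph = [p + off for p in base_periph]
            g.add_edges_from((p, hub) for p in rep_periph)
            new_periph.extend(rep_periph)
        peripheral = new_periph
    return g, {"hub": hub, "peripheral": peripheral}


def _triangle_hierarchy(levels: int, pendants: int, seed) -> tuple[nx.Graph, dict]:
    """Planted binary hierarchy whose terminal communities are triangles.

    The base unit is a triangle; at each of ``levels`` doublings two copies
    of the current module are joined by a single bridge edge, giving
    3 * 2**levels core nodes organized in nested communities of sizes
    3, 6, 12, ...  ``pendants`` degree-1 nodes are then attached to random
    core nodes (they join their anchor's community at every level).

    truth["level_blocks"][l] is the planted partition after l+1 bisections
    (finest = the triangles); truth["triangles"] lists the terminal motifs.
    """
    if levels < 1:
        raise ValueError("need levels >= 1")
    g = nx.Graph([(0, 1), (0, 2), (1, 2)])
    port, n = 1, 3
    for _ in range(levels):
        h = nx.relabel_nodes(g, {u: u + n for u in g.nodes})
        g = nx.compose(g, h)
        g.add_edge(port, port + n)
        n *= 2
    n_core = n
    anchors = {}
    if pendants:
        rng = np.random.default_rng(seed)
        for anchor in rng.choice(n_core, size=int(pendants), replace=False):
            g.add_edge(int(anchor), n)
            anchors[n] = int(anchor)
            n += 1

    def block_of(node: int, width: int) -> int:
        core = anchors.get(node, node)
        return core // width

    level_blocks = []
    for lvl in range(1, levels + 1):
        width = 3 * 2 ** (levels - lvl)
        blocks: dict = {}
        for node in g.nodes:
            blocks.setdefault(block_of(node, width), set()).add(node)
        level_blocks.append(sorted(blocks.values(), key=lambda b: min(b)))
    triangles = [set(range(i, i + 3)) for i in range(0, n_core, 3)]
    return g, {"level_blocks": level_blocks, "triangles": triangles}


def gen_graph(model: str, seed: int | None = None, **params) -> tuple[nx.Graph, dict]:
    """Generate a graph with ground truth.

    Models
    ------
    ba : Barabasi-Albert preferential attachment; params n, m.
    er : Erdos-Renyi G(n, p) null; params n, p.
    planted_partition : blocks of equal size; params blocks, block_size,
        p_in, p_out; truth["blocks"] lists the planted node sets.
    hierarchical : deterministic Ravasz-style clique replication; params
        motif_size (default 5), levels (default 2).
    triangle_hierarchy : planted nested bisections terminating in triangle
        motifs; params levels (default 4), pendants (default 0).
    """
    if model == "ba":
        n, m = int(params["n"]), int(params["m"])
        if n < m + 1 or m < 1:
            raise ValueError("ba requires n > m >= 1")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
        truth = {}
    elif model == "er":
        n, p = int(params["n"]), float(params["p"])
        if not (0 <= p <= 1) or n < 1:
            raise ValueError("er requires n >= 1 and p in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
        truth = {}
    elif model == "planted_partition":
        blocks = int(params["blocks"])
        size = int(params["block_size"])
        p_in = float(params["p_in"])
        p_out = float(params["p_out"])
        if blocks < 2 or size < 1 or not (0 <= p_out <= p_in <= 1):
            raise ValueError("planted_partition requires blocks >= 2 and 0 <= p_out <= p_in <= 1")
        g = nx.planted_partition_graph(blocks, size, p_in, p_out, seed=seed)
        truth = {
            "blocks": [set(range(b * size, (b + 1) * size)) for b in range(blocks)]
        }
    elif model == "hierarchical":
        g, truth = _hierarchical_graph(
            int(params.get("motif_size", 5)), int(params.get("levels", 2))
        )
    elif model == "triangle_hierarchy":
        g, truth = _triangle_hierarchy(
            int(params.get("levels", 4)), int(params.get("pendants", 0)), seed
        )
    else:
        raise ValueError(f"unknown graph model {model!r}")
    g = nx.Graph(g)  # strip any generator bookkeeping; simple undirected
    g.remove_edges_from(nx.selfloop_edges(g))
    return g, truth


def graph_to_interactions(
    graph: nx.Graph, score: float = 1.0, names=None
) -> pd.DataFrame:
    """Emit a graph as a scored interaction table (plain dialect).

    ``names`` optionally maps graph nodes to gene symbols.
    """
    label = (lambda n: str(names[n])) if names is not None else str
    rows = sorted(
        (min(label(a), label(b)), max(label(a), label(b)), score)
        for a, b in graph.edges
    )
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])


def sample_powerlaw(
    alpha: float, xmin: float, n: int, discrete: bool, seed: int | None = None
) -> np.ndarray:
    """Exact power-law samples: inverse-CDF (continuous Pareto) or
    inverse-CDF lookup in the Hurwitz-zeta pmf (discrete)."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if xmin <= 0 or n < 1:
        raise ValueError("xmin must be positive and n >= 1")
    rng = np.random.default_rng(seed)
    draw = power_law_tail_sampler(alpha, xmin, discrete)
    return draw(rng, int(n))
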