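"""Recursive leading-eigenvector (LEV) community decomposition.

Newman's spectral bisection works on the modularity matrix
B_ij = A_ij - k_i k_j / 2m.  For a subset g of nodes the generalized matrix

    B_g(i,j) = B_ij - delta_ij * sum_{l in g} B_il

is used, so repeated bisection of sub-communities optimizes the global
modularity Q.  A community splits along the sign pattern of the leading
eigenvector of B_g; the split is accepted only when the leading eigenvalue
and the modularity gain delta_Q = s^T B_g s / 4m are both positive and both
sides are non-empty.

Applied recursively, this yields a hierarchy of nested communities down to
terminal triangle motifs — subgraphs of 3 nodes and 3 edges, G(3,3) — which
are the unit of the key-regulator tracing.  Tree nodes carry dotted path
labels (root "C", children "C1", "C2", ..., grandchildren "C2.3", ...).

Communities with no internal triangle are retained in the tree but flagged
``has_motif=False``; downstream key-regulator extraction consumes only the
triangle leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "modularity",
    "lev_split",
    "find_triangles",
    "recursive_decompose",
    "label_paths",
    "parse_label",
    "SplitResult",
    "CommunityNode",
    "DecompositionTree",
]

_EIG_TOL = 1e-10
_Q_TOL = 1e-12


def modularity(graph: nx.Graph, partition) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2].

    ``partition`` is an iterable of node collections covering every node
    exactly once; the graph must have at least one edge.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("graph has no edges")
    communities = [set(c) for c in partition]
    seen: set = set()
    for c in communities:
        if seen & c:
            raise ValueError("partition assigns some node twice")
        seen |= c
    missing = set(graph.nodes) - seen
    if missing:
        raise ValueError(f"nodes missing from partition: {sorted(map(str, missing))[:5]}")
    extra = seen - set(graph.nodes)
    if extra:
        raise ValueError(f"partition contains unknown nodes: {sorted(map(str, extra))[:5]}")
    q = 0.0
    for c in communities:
        e_c = sum(1 for a, b in graph.edges(c) if a in c and b in c)
        d_c = sum(d for _, d in graph.degree(c))
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


@dataclass
class SplitResult:
    eigenvalue_1: float
    sign_vector: dict  # node -> +1 / -1
    delta_Q: float
    divisible: bool

    def sides(self) -> tuple[list, list]:
        pos = [n for n, s in self.sign_vector.items() if s > 0]
        neg = [n for n, s in self.sign_vector.items() if s < 0]
        return pos, neg


def _leading_eig(b: np.ndarray, tol: float = _EIG_TOL, max_iter: int = 10000):
    """Leading (most positive) eigenpair of a symmetric matrix.

    Power iteration on B + cI with a Gershgorin shift c (making the most
    positive eigenvalue dominant in magnitude), from a fixed deterministic
    start vector; falls back to a dense symmetric eigendecomposition when the
    iteration has not converged within ``max_iter``.
    """
    n = b.shape[0]
    c = float(np.max(np.sum(np.abs(b), axis=1))) + 1.0
    v = np.sin(np.arange(1, n + 1, dtype=float))  # deterministic, generic
    norm = np.linalg.norm(v)
    if norm == 0:
        v = np.ones(n)
        norm = np.sqrt(n)
    v /= norm
    for _ in range(max_iter):
        w = b @ v + c * v
        wn = np.linalg.norm(w)
        if wn == 0:  # v in the kernel of the shifted matrix
            break
        w /= wn
        if np.linalg.norm(w - v) < tol:
            v = w
            lam = float(v @ (b @ v))
            if np.max(np.abs(b @ v - lam * v)) <= 1e-9:
                return lam, v
            break
        v = w
    # slow convergence (near-degenerate leading pair): exact dense solve
    w, vecs = np.linalg.eigh(b)
    return float(w[-1]), vecs[:, -1]


def lev_split(graph: nx.Graph, member_subset=None) -> SplitResult:
    """Propose a bisection of ``member_subset`` (default: all nodes) by the
    sign pattern of the leading eigenvector of the generalized modularity
    matrix.  Zero eigenvector entries go to the positive side."""
    members = sorted(graph.nodes, key=str) if member_subset is None else sorted(member_subset, key=str)
    if len(members) < 2:
        raise ValueError("member subset must contain at least 2 nodes")
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("graph has no edges")
    k = np.array([graph.degree(n) for n in members], dtype=float)
    a = nx.to_numpy_array(graph, nodelist=members, weight=None)
    b = a - np.outer(k, k) / (2.0 * m)
    b[np.diag_indices_from(b)] -= b.sum(axis=1)  # generalized correction

    lam, vec = _leading_eig(b)
    s = np.where(vec >= 0, 1.0, -1.0)  # zeros to the positive side
    delta_q = float(s @ (b @ s)) / (4.0 * m)
    both = (s > 0).any() and (s < 0).any()
    divisible = bool(lam > _EIG_TOL and delta_q > _Q_TOL and both)
    return SplitResult(
        eigenvalue_1=float(lam),
        sign_vector={n: int(si) for n, si in zip(members, s)},
        delta_Q=delta_q,
        divisible=divisible,
    )


def kl_refine(graph: nx.Graph, split: SplitResult) -> SplitResult:
    """Greedy single-node refinement of a proposed bisection.

    Flips the node giving the largest positive modularity gain until no
    single flip improves (flips that would empty a side are disallowed).
    The result is a single-flip local optimum.
    """
    members = sorted(split.sign_vector, key=str)
    m = graph.number_of_edges()
    k = np.array([graph.degree(n) for n in members], dtype=float)
    a = nx.to_numpy_array(graph, nodelist=members, weight=None)
    b = a - np.outer(k, k) / (2.0 * m)
    b[np.diag_indices_from(b)] -= b.sum(axis=1)
    s = np.array([split.sign_vector[n] for n in members], dtype=float)

    while True:
        bs = b @ s
        # flipping node i changes s^T B s by 4*(B_ii - s_i * (Bs)_i)
        gains = 4.0 * (np.diag(b) - s * bs)
        order = np.argsort(-gains)
        flipped = False
        for i in order:
            if gains[i] <= _Q_TOL * 4.0 * m:
                break
            side = s[i]
            if np.sum(s == side) <= 1:  # would empty a side
                continue
            s[i] = -s[i]
            flipped = True
            break
        if not flipped:
            break

    delta_q = float(s @ (b @ s)) / (4.0 * m)
    both = (s > 0).any() and (s < 0).any()
    divisible = bool(delta_q > _Q_TOL and both)
    return SplitResult(
        eigenvalue_1=split.eigenvalue_1,
        sign_vector={n: int(si) for n, si in zip(members, s)},
        delta_Q=delta_q,
        divisible=divisible,
    )


def find_triangles(graph: nx.Graph, member_subset=None) -> list[frozenset]:
    """All triangles (3-node, 3-edge subgraphs) within the subset, each once."""
    members = set(graph.nodes) if member_subset is None else set(member_subset)
    sub = graph.subgraph(members)
    order = {n: i for i, n in enumerate(sorted(sub.nodes, key=str))}
    triangles = []
    for u in sub.nodes:
        for v in sub.neighbors(u):
            if order[v] <= order[u]:
                continue
            for w in sub.neighbors(u):
                if order[w] <= order[v]:
                    continue
                if sub.has_edge(v, w):
                    triangles.append(frozenset((u, v, w)))
    return triangles


@dataclass
class CommunityNode:
    label: str
    level: int
    members: tuple
    has_motif: bool
    is_motif_leaf: bool
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "level": self.level,
            "members": list(self.members),
            "has_motif": self.has_motif,
            "is_motif_leaf": self.is_motif_leaf,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class DecompositionTree:
    root: CommunityNode
    max_level: int
    motif_leaves: list

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "max_level": self.max_level,
            "motif_leaves": [leaf.label for leaf in self.motif_leaves],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def leaves(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out


def child_label(parent_label: str, index: int) -> str:
    """Dotted path labels: C -> C2 -> C2.3 -> C2.3.4 -> C2.3.4.1."""
    if parent_label == "C":
        return f"C{index}"
    return f"{parent_label}.{index}"


def parse_label(label: str) -> tuple[int, ...]:
    """Inverse of the label grammar: "C2.3.4.1" -> (2, 3, 4, 1)."""
    if not label.startswith("C"):
        raise ValueError(f"bad label {label!r}")
    body = label[1:]
    if not body:
        return ()
    return tuple(int(part) for part in body.split("."))


def _order_subsets(subsets: list[list]) -> list[list]:
    """Children ordered by decreasing size, ties by smallest member symbol."""
    return sorted(subsets, key=lambda s: (-len(s), min(map(str, s))))


def recursive_decompose(
    graph: nx.Graph,
    max_level: int | None = None,
    refine: str = "none",
    mode: str = "subgraph",
) -> DecompositionTree:
    """Recursively bisect the graph down to G(3,3) triangle motifs.

    The root holds the whole graph at level 0 (label "C").  A community
    becomes a leaf when it is exactly a triangle, has fewer than 3 members,
    reaches ``max_level``, or the LEV split declares it indivisible.
    Disconnected member sets (including a disconnected input graph) get one
    child per connected component, largest first.

    ``mode`` selects the divisibility criterion for sub-communities:

    * ``"subgraph"`` (default) — each community's induced subgraph is
      re-analyzed as a standalone graph (its own modularity null model).
      This escapes the resolution limit of global modularity and lets the
      recursion reach terminal triangles, matching per-level re-application
      of LEV community detection.
    * ``"global"`` — the generalized modularity matrix B_g of the full
      graph; every accepted split then strictly increases the global Q, but
      small deep communities typically become indivisible long before the
      motif scale.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if refine not in ("none", "kl"):
        raise ValueError(f"unknown refine mode {refine!r}")
    if mode not in ("subgraph", "global"):
        raise ValueError(f"unknown mode {mode!r}")

    motif_leaves: list[CommunityNode] = []
    deepest = [0]

    def build(members: list, level: int, label: str) -> CommunityNode:
        members = sorted(members, key=str)
        tri = find_triangles(graph, members)
        motif_leaf = len(members) == 3 and len(tri) == 1
        node = CommunityNode(
            label=label,
            level=level,
            members=tuple(members),
            has_motif=bool(tri),
            is_motif_leaf=motif_leaf,
        )
        deepest[0] = max(deepest[0], level)
        if motif_leaf:
            motif_leaves.append(node)
            return node
        if len(members) < 3 or (max_level is not None and level >= max_level):
            return node

        sub = graph.subgraph(members)
        comps = [sorted(c, key=str) for c in nx.connected_components(sub)]
        if len(comps) > 1:
            subsets = comps
        else:
            if mode == "subgraph":
                frozen = nx.Graph(sub)
                if frozen.number_of_edges() == 0:
                    return node
                split = lev_split(frozen)
                if refine == "kl" and len(set(split.sign_vector.values())) == 2:
                    refined = kl_refine(frozen, split)
                    if refined.divisible:
                        split = refined
            else:
                split = lev_split(graph, members)
                if refine == "kl" and len(set(split.sign_vector.values())) == 2:
                    refined = kl_refine(graph, split)
                    if refined.divisible:
                        split = refined
            if not split.divisible:
                return node
            pos, neg = split.sides()
            subsets = [pos, neg]
        for idx, subset in enumerate(_order_subsets(subsets), start=1):
            node.children.append(build(subset, level + 1, child_label(label, idx)))
        return node

    root = build(sorted(graph.nodes, key=str), 0, "C")
    return DecompositionTree(root=root, max_level=deepest[0], motif_leaves=motif_leaves)


def label_paths(tree: DecompositionTree) -> list[tuple[str, list]]:
    """One (leaf_label, sorted member list) row per triangle motif leaf."""
    return [(leaf.label, sorted(leaf.members, key=str)) for leaf in tree.motif_leaves]
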