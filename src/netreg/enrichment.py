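"""Hypergeometric over-representation analysis (ORA) against GMT gene sets.

For a query of n genes drawn from a universe of N genes, and a gene set with
K members in the universe of which k overlap the query, the one-sided
enrichment p-value is P[X >= k] for X ~ Hypergeometric(N, K, n) and the fold
enrichment is (k/n) / (K/N).  p-values are Benjamini-Hochberg adjusted across
all sets in the collection queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .degs import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "hypergeom_ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe.

    ``sets`` maps name -> (description, member frozenset); members outside
    the universe are dropped at construction with a logged count, and sets
    left empty are removed.
    """

    sets: dict = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.universe = frozenset(map(str, self.universe))
        restricted = {}
        n_dropped = 0
        for name, (desc, members) in self.sets.items():
            members = frozenset(map(str, members))
            kept = members & self.universe
            n_dropped += len(members) - len(kept)
            if kept:
                restricted[name] = (desc, kept)
            else:
                logger.warning("dropping empty gene set %r after universe restriction", name)
        if n_dropped:
            logger.warning("dropped %d set members outside the universe", n_dropped)
        self.sets = restricted

    def restrict(self, universe) -> "GeneSetCollection":
        return GeneSetCollection(dict(self.sets), frozenset(universe))

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...).

    Duplicate members within a set are collapsed; empty sets are dropped with
    a warning.  When ``universe`` is None it defaults to the union of all set
    members.
    """
    sets: dict = {}
    union: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                logger.warning("GMT line %d: empty set %r dropped", lineno, name)
                continue
            sets[name] = (desc, members)
            union |= members
    return GeneSetCollection(sets, frozenset(universe) if universe is not None else frozenset(union))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc, members = collection.sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_ora(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of the collection.

    Query genes outside the universe are dropped with a warning.  Returns a
    DataFrame sorted by p-value with columns set_name, description, genes,
    overlap_k, query_n, set_K, universe_N, p_value, fdr, fold_enrichment.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    query = set(map(str, query))
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    if not query:
        raise ValueError("empty query after universe restriction")

    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, (desc, members) in collection.sets.items():
        k_set = len(members)
        overlap = query & members
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, n_universe, k_set, n_query))
        fold = (k / n_query) / (k_set / n_universe)
        rows.append(
            {
                "set_name": name,
                "description": desc,
                "genes": ",".join(sorted(overlap)),
                "overlap_k": k,
                "query_n": n_query,
                "set_K": k_set,
                "universe_N": n_universe,
                "p_value": p,
                "fold_enrichment": fold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "description",
            "genes",
            "overlap_k",
            "query_n",
            "set_K",
            "universe_N",
            "p_value",
            "fold_enrichment",
        ],
    )
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


def write_enrichment_tsv(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)
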