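"""Key-regulator extraction from a decomposition tree.

A key regulator is a gene that persists from the root of the hierarchical
decomposition down to a terminal G(3,3) triangle motif.  Because the
decomposition partitions are nested, membership in a terminal triangle leaf
is equivalent to having an ancestor community at every level, so the
regulator set is simply the union of motif-leaf members and the regulator
count is exactly 3 x (number of motif leaves).

:func:`regulator_summary` joins each regulator with its topological
statistics from the primary network and flags "low-degree bridge" nodes:
low-degree regulators whose motif partner is a hub (defaults k <= 11 next to
a partner with k >= 17 — report heuristics, not part of the definition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import DecompositionTree

__all__ = ["extract_key_regulators", "regulator_summary"]


def extract_key_regulators(tree: DecompositionTree) -> pd.DataFrame:
    """One row per key regulator: gene, leaf_label, partner_1, partner_2.

    Motif leaves are disjoint (nested partitions), so every regulator appears
    exactly once.
    """
    rows = []
    for leaf in tree.motif_leaves:
        members = sorted(leaf.members, key=str)
        for gene in members:
            partners = [g for g in members if g != gene]
            rows.append(
                {
                    "gene": gene,
                    "leaf_label": leaf.label,
                    "partner_1": partners[0],
                    "partner_2": partners[1],
                }
            )
    df = pd.DataFrame(rows, columns=["gene", "leaf_label", "partner_1", "partner_2"])
    return df.set_index("gene")


def regulator_summary(
    records: pd.DataFrame,
    metrics: pd.DataFrame,
    bridge_k_max: int = 11,
    hub_k_min: int = 17,
    round_digits: int | None = 4,
) -> pd.DataFrame:
    """Join regulators with their node metrics (k, C_B, C_C, C).

    ``low_degree_bridge`` is True when the regulator's degree is at most
    ``bridge_k_max`` and at least one motif partner's degree is at least
    ``hub_k_min``.  Centrality columns are rounded (round-half-even) to
    ``round_digits`` places for report output; pass None to keep full
    precision.
    """
    missing = [g for g in records.index if g not in metrics.index]
    if missing:
        raise ValueError(f"metrics missing for gene(s): {missing[:5]}")
    out = records.copy()
    out["k"] = metrics.loc[out.index, "k"].astype(int)
    for col in ("C_B", "C_C", "C"):
        out[col] = metrics.loc[out.index, col].astype(float)
    partner_k = np.maximum(
        metrics.loc[out["partner_1"], "k"].to_numpy(),
        metrics.loc[out["partner_2"], "k"].to_numpy(),
    )
    out["low_degree_bridge"] = (out["k"] <= bridge_k_max) & (partner_k >= hub_k_min)
    if round_digits is not None:
        for col in ("C_B", "C_C", "C"):
            out[col] = np.round(out[col], round_digits)
    return out


def write_keyreg_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index_label="gene")


def read_keyreg_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
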