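"""Differential-expression screening for a two-group design.

The screen is the classic moderated-t workflow: per-gene log2 fold change
(difference of log2 group means), a two-sample t-statistic whose gene-wise
pooled variance is shrunk toward a common prior by empirical Bayes, and
Benjamini-Hochberg control of the FDR.  Genes pass when

    |log2FC| >= 1,   p < 0.05,   p_adj <= 0.05

with exactly that comparison strictness (the defaults; all three are
configurable).

Empirical-Bayes moderation follows Smyth's hierarchical model: with d residual
degrees of freedom per gene and sample variances s_g^2, the posterior variance
is

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated t is referred to a t distribution on d + d0 degrees of
freedom.  The prior (d0, s0^2) is estimated by moment matching on log s_g^2
(an F-distribution fit).  Setting ``test="ordinary"`` forces d0 = 0, i.e. the
ordinary pooled-variance two-sample t-test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "log2_fold_change",
    "moderated_t",
    "bh_adjust",
    "deg_table",
    "filter_degs",
    "screen_degs",
]


def log2_fold_change(
    matrix: ExpressionMatrix, scale: str = "log2", pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2 fold change, case minus control.

    On log2-scale input this is the difference of group means, which equals the
    log2 ratio of geometric means on the linear scale.  With ``scale="linear"``
    values are first transformed as log2(x + pseudocount).
    """
    if scale not in ("log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    for g in (CONTROL, CASE):
        if not matrix.samples_in(g):
            raise ValueError(f"empty group: {g!r}")
    values = matrix.values
    if scale == "linear":
        arr = values.to_numpy(dtype=float)
        if (arr + pseudocount <= 0).any():
            raise ValueError("non-positive values after pseudocount; cannot log-transform")
        values = pd.DataFrame(
            np.log2(arr + pseudocount), index=values.index, columns=values.columns
        )
    case_mean = values[matrix.samples_in(CASE)].mean(axis=1)
    ctrl_mean = values[matrix.samples_in(CONTROL)].mean(axis=1)
    lfc = case_mean - ctrl_mean
    lfc.name = "log2fc"
    return lfc


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the monotone map)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior for gene variances.

    Returns (d0, s0^2); d0 = inf when the observed spread of log variances is
    no larger than expected from chi-square sampling noise alone.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(float(evar))
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_t(matrix: ExpressionMatrix, test: str = "moderated") -> pd.DataFrame:
    """Per-gene (t, p) for case vs control.

    Returns a DataFrame with columns ``t``, ``p``, plus the shrinkage
    hyperparameters ``d0`` and ``s0sq`` as attrs.  ``test="ordinary"``
    disables shrinkage (d0 = 0).
    """
    if test not in ("moderated", "ordinary"):
        raise ValueError(f"unknown test {test!r}")
    case = matrix.group_values(CASE).to_numpy(dtype=float)
    ctrl = matrix.group_values(CONTROL).to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], case.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group for variance estimation")
    d = n1 + n2 - 2
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (case - case.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    if np.all(s2 == 0):
        raise ValueError("degenerate variance: zero residual variance for all genes")

    if test == "ordinary":
        d0, s0sq = 0.0, 0.0
        s2_post = s2
        df_total = float(d)
    else:
        d0, s0sq = _fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0sq + d * s2) / (d0 + d)
            df_total = float(d + d0)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(diff == 0, 0.0, t)  # identical groups => t = 0 even if se = 0
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df_total))
    out = pd.DataFrame({"t": t, "p": p}, index=matrix.values.index)
    out.attrs["d0"] = d0
    out.attrs["s0sq"] = s0sq
    out.attrs["df_total"] = df_total
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1.

    Order-preserving with the input indexing; the classic p_(i) * n / i with a
    cumulative minimum taken from the largest rank down.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def deg_table(
    matrix: ExpressionMatrix,
    test: str = "moderated",
    scale: str = "log2",
    pseudocount: float = 1.0,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Full annotated DEG table for every gene.

    Columns: gene (index), log2fc, t, p, padj, direction.  ``direction`` is
    ``up``/``down`` only for genes passing all three filters, else ``none``.
    Genes with missing values are dropped with a logged warning.
    """
    matrix = matrix.drop_incomplete_genes()
    lfc = log2_fold_change(matrix, scale=scale, pseudocount=pseudocount)
    if scale == "linear":
        arr = np.log2(matrix.values.to_numpy(dtype=float) + pseudocount)
        matrix = ExpressionMatrix(
            pd.DataFrame(arr, index=matrix.values.index, columns=matrix.values.columns),
            matrix.groups,
        )
    tp = moderated_t(matrix, test=test)
    table = pd.DataFrame({"log2fc": lfc, "t": tp["t"], "p": tp["p"]})
    table["padj"] = bh_adjust(table["p"].to_numpy())
    passes = (
        (table["log2fc"].abs() >= lfc_min)
        & (table["p"] < p_max)
        & (table["padj"] <= padj_max)
    )
    table["direction"] = np.where(
        passes & (table["log2fc"] > 0), "up", np.where(passes & (table["log2fc"] < 0), "down", "none")
    )
    table.index.name = "gene"
    table.attrs.update(tp.attrs)
    return table


def filter_degs(
    table: pd.DataFrame,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Retain records with |log2fc| >= lfc_min AND p < p_max AND padj <= padj_max.

    The returned table carries ``n_up``/``n_down`` counts in ``attrs``.
    Empty input yields an empty table with zero counts.
    """
    if len(table) == 0:
        out = table.copy()
        out.attrs["n_up"] = 0
        out.attrs["n_down"] = 0
        return out
    keep = (
        (table["log2fc"].abs() >= lfc_min)
        & (table["p"] < p_max)
        & (table["padj"] <= padj_max)
    )
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.attrs["n_up"] = int((out["direction"] == "up").sum())
    out.attrs["n_down"] = int((out["direction"] == "down").sum())
    return out


def screen_degs(matrix: ExpressionMatrix, **kwargs) -> pd.DataFrame:
    """Convenience: full table then filter, returning only passing genes."""
    table = deg_table(matrix, **kwargs)
    return filter_degs(
        table,
        lfc_min=kwargs.get("lfc_min", 1.0),
        p_max=kwargs.get("p_max", 0.05),
        padj_max=kwargs.get("padj_max", 0.05),
    )


def write_deg_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def read_deg_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index = df.index.astype(str)
    return df
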