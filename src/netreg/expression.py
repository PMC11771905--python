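"""Two-group expression matrices.

The container is a thin wrapper around a genes x samples :class:`pandas.DataFrame`
of log2-scale values plus a control/case label per sample.  It is the input to
the differential-expression screen in :mod:`netreg.degs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
_VALID_GROUPS = {CONTROL, CASE}


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a two-group design.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbols, columns are sample names.
        Values are expected on log2 scale (see :func:`netreg.degs.log2_fold_change`
        for linear-scale input handling).
    groups
        Mapping (dict or Series) from sample name to ``"control"`` / ``"case"``.
        Every sample must be assigned exactly one group and both groups must be
        non-empty.
    """

    values: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dups[:5]}")
        self.groups = pd.Series(self.groups, dtype=object)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]
        bad = sorted(set(self.groups) - _VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected {sorted(_VALID_GROUPS)}")
        for g in _VALID_GROUPS:
            if not (self.groups == g).any():
                raise ValueError(f"empty group: {g!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def drop_incomplete_genes(self) -> "ExpressionMatrix":
        """Drop genes carrying any non-finite value, with a logged warning."""
        finite = np.isfinite(self.values.to_numpy()).all(axis=1)
        n_drop = int((~finite).sum())
        if n_drop:
            logger.warning("dropping %d genes with missing/non-finite values", n_drop)
            return ExpressionMatrix(self.values.loc[finite], self.groups)
        return self


def read_expression_tsv(matrix_path, groups_path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = gene symbol, header =
    sample names) and a two-column sample<TAB>group file."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"], comment="#"
    )
    if groups["sample"].duplicated().any():
        raise ValueError("duplicate sample rows in group file")
    return ExpressionMatrix(values, pd.Series(groups["group"].values, index=groups["sample"]))


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    matrix.groups.rename("group").to_csv(groups_path, sep="\t", header=False)
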