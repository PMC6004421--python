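"""Expression dataset container shared by every analysis stage.

The container pairs a genes-by-samples expression matrix with a sample
metadata table (group label plus covariates).  Expression values are assumed
to be normalized already (e.g. variance-stabilized counts); no normalization
is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_COLUMN = "group"


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with aligned sample metadata.

    Parameters
    ----------
    expression : DataFrame
        Rows indexed by gene symbol, columns by sample id.
    samples : DataFrame
        Indexed by sample id; must contain a ``group`` column.  Any further
        columns are treated as covariates (numeric or categorical).
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if GROUP_COLUMN not in self.samples.columns:
            raise ValueError(f"sample metadata must contain a {GROUP_COLUMN!r} column")
        if not self.expression.columns.equals(self.samples.index):
            if set(self.expression.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample metadata index disagree")
            self.samples = self.samples.loc[self.expression.columns]
        if self.expression.index.has_duplicates:
            dup = self.expression.index[self.expression.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols in expression matrix: {dup}")

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.samples[GROUP_COLUMN]))

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.samples.columns if c != GROUP_COLUMN]

    def subset_group(self, group: str) -> "ExpressionDataset":
        mask = self.samples[GROUP_COLUMN] == group
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return ExpressionDataset(self.expression.loc[:, mask.to_numpy()], self.samples.loc[mask])

    def by_group(self) -> dict[str, "ExpressionDataset"]:
        return {g: self.subset_group(g) for g in self.groups}

    def values_for(self, genes: list[str]) -> np.ndarray:
        """Samples x genes value matrix for the requested genes."""
        missing = [g for g in genes if g not in self.expression.index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing}")
        return self.expression.loc[genes].to_numpy(dtype=float).T

    def covariate_matrix(self, covariates: list[str]) -> np.ndarray:
        """Samples x covariates numeric matrix (categoricals must be pre-encoded)."""
        missing = [c for c in covariates if c not in self.samples.columns]
        if missing:
            raise KeyError(f"covariates absent from metadata: {missing}")
        block = self.samples[covariates]
        non_numeric = [c for c in covariates if not pd.api.types.is_numeric_dtype(block[c])]
        if non_numeric:
            raise ValueError(f"covariates must be numeric for SEM use: {non_numeric}")
        return block.to_numpy(dtype=float)

    # -- i/o -------------------------------------------------------------
    def to_tsv(self, expression_path: str | Path, samples_path: str | Path) -> None:
        self.expression.to_csv(expression_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, expression_path: str | Path, samples_path: str | Path) -> "ExpressionDataset":
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(expr, meta)


def concat_genes(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Stack datasets that share samples but carry disjoint gene sets."""
    if not datasets:
        raise ValueError("need at least one dataset")
    base = datasets[0]
    for other in datasets[1:]:
        if not other.expression.columns.equals(base.expression.columns):
            raise ValueError("datasets must share identical sample columns")
        overlap = set(base.expression.index) & set(other.expression.index)
        if overlap:
            raise ValueError(f"gene sets overlap: {sorted(overlap)[:5]} ...")
    expr = pd.concat([d.expression for d in datasets], axis=0)
    return ExpressionDataset(expr, base.samples.copy())
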