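"""Core in-memory containers shared by every pipeline stage.

The substrate of the whole analysis is a log2 expression matrix (genes x
samples) with per-sample metadata (case/control group and batch id), plus a
train/test sample split and, optionally, a sample x cell-type fraction matrix
from immune deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "DILI"
CONTROL = "control"
GROUPS = (CASE, CONTROL)


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes as rows and samples as columns.

    Parameters
    ----------
    values
        DataFrame of finite log2 intensities; index = gene ids,
        columns = sample ids, both unique.
    sample_meta
        DataFrame indexed by sample id with columns ``group`` (one of
        ``"DILI"``/``"control"``) and ``batch``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            bad = self.values.stack(future_stack=True)
            bad = bad[~np.isfinite(bad)]
            gene, sample = bad.index[0]
            raise ValueError(f"non-finite expression value at gene {gene!r}, sample {sample!r}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in ("group", "batch"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        bad_groups = set(self.sample_meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Group label per sample, aligned to the matrix column order."""
        return self.sample_meta.loc[self.values.columns, "group"]

    def batches(self) -> pd.Series:
        """Batch label per sample, aligned to the matrix column order."""
        return self.sample_meta.loc[self.values.columns, "batch"]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(sample_ids)],
            sample_meta=self.sample_meta.loc[list(sample_ids)],
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, sample_meta=self.sample_meta)


@dataclass
class SampleSplit:
    """Stratified train/test partition of the samples.

    ``ratio`` is the train fraction; the default seed (234) follows the
    convention of seeding the split for reproducibility.
    """

    train_ids: list[str]
    test_ids: list[str]
    ratio: float = 0.8
    seed: int = 234

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")

    @property
    def all_ids(self) -> list[str]:
        return list(self.train_ids) + list(self.test_ids)


@dataclass
class CellFractionMatrix:
    """Per-sample immune cell-type fractions (rows sum to 1).

    ``values``: DataFrame indexed by sample id, one column per cell type.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("cell fractions must be nonnegative")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = self.values.index[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"cell fractions of sample {bad!r} do not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)
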