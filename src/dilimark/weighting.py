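"""Normalized overall weights: the ensemble's aggregation statistic.

Each model's absolute importances are divided by that model's maximum absolute
importance, so every model contributes on a common [0, 1] scale with its top
gene at exactly 1.  The overall weight of a gene is the sum of its six
normalized weights,

    total(g) = sum_m |w_m(g)| / max_g' |w_m(g')|,   0 <= total <= 6,

and diagnostic genes are those whose overall weight exceeds a threshold
(default 3, i.e. the gene must carry, on average, at least half of every
model's top importance).  A model whose importances are all zero (the lasso
routinely zeroes everything on null data) contributes a zero column rather
than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ImportanceVector

#: canonical column order of the weight table
MODEL_ORDER = ["lasso", "svm_linear", "random_forest", "neural_net", "gbm", "decision_tree"]


@dataclass
class WeightTable:
    """Gene x model normalized importances plus row totals.

    ``normalized`` is a DataFrame (index = gene, columns = models, values in
    [0, 1]; each nonzero column has max exactly 1); ``total`` the row sums.
    """

    normalized: pd.DataFrame
    total: pd.Series
    threshold: float = 3.0

    def __post_init__(self) -> None:
        arr = self.normalized.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1 + 1e-12).any():
            raise ValueError("normalized weights must lie in [0, 1]")
        col_max = arr.max(axis=0)
        bad = [
            c
            for c, m in zip(self.normalized.columns, col_max)
            if m > 0 and abs(m - 1.0) > 1e-9
        ]
        if bad:
            raise ValueError(f"nonzero model columns must have max 1: {bad}")
        if not np.allclose(self.total.to_numpy(), arr.sum(axis=1), atol=1e-9):
            raise ValueError("totals do not equal row sums")

    @property
    def genes(self) -> list[str]:
        return list(self.normalized.index)

    @property
    def models(self) -> list[str]:
        return list(self.normalized.columns)


def normalize_importances(vectors: list[ImportanceVector]) -> WeightTable:
    """Max-normalize each model's importances and sum across models.

    All vectors must cover the same gene universe; columns follow the
    canonical model order where applicable, otherwise input order.
    """
    if not vectors:
        raise ValueError("no importance vectors given")
    universe = set(vectors[0].raw.index)
    for v in vectors[1:]:
        if set(v.raw.index) != universe:
            diff = sorted(universe.symmetric_difference(set(v.raw.index)))
            raise ValueError(f"gene universes differ (model {v.model}): {diff}")

    genes = list(vectors[0].raw.index)
    order = [m for m in MODEL_ORDER if m in {v.model for v in vectors}]
    by_model = {v.model: v for v in vectors}
    ordered = [by_model[m] for m in order] + [v for v in vectors if v.model not in order]

    columns = {}
    for v in ordered:
        raw = v.raw.reindex(genes).abs().to_numpy(dtype=float)
        top = raw.max()
        columns[v.model] = raw / top if top > 0 else raw
    normalized = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    return WeightTable(normalized=normalized, total=normalized.sum(axis=1))


def select_genes(table: WeightTable, threshold: float | None = None) -> list[str]:
    """Genes with overall weight strictly above the threshold.

    Ordered by total descending, ties broken by gene id ascending.
    """
    thr = table.threshold if threshold is None else threshold
    selected = table.total[table.total > thr]
    ordered = selected.to_frame("total").reset_index()
    ordered = ordered.sort_values(["total", "gene"], ascending=[False, True])
    return ordered["gene"].tolist()


def weight_table_from_raw(raw: pd.DataFrame, threshold: float = 3.0) -> WeightTable:
    """Build a WeightTable from a gene x model matrix of raw importances.

    Convenience for re-aggregating an externally supplied importance matrix
    (e.g. a published per-model weight table) through the same normalization
    and summation path as live model fits.
    """
    vectors = [
        ImportanceVector(model=str(col), raw=raw[col].abs(), train_error=0.0, test_error=0.0)
        for col in raw.columns
    ]
    table = normalize_importances(vectors)
    table.threshold = threshold
    return table
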