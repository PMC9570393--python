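"""Bundled reference data.

The package ships one small reference table: published per-model normalized
importance weights for 21 DILI-associated genes across the six ensemble
models, with the reported overall weights.  It serves as a fixed regression
target for the normalization/aggregation statistic — feeding the per-model
columns back through :func:`dilimark.weighting.weight_table_from_raw` must
recover the published totals to rounding precision.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: the four published diagnostic genes (overall weight > 3)
REFERENCE_DIAGNOSTIC_GENES = ["DDIT3", "GADD45A", "RBM24", "SLC3A2"]


def load_reference_weights() -> pd.DataFrame:
    """Load the reference weight table.

    Returns a DataFrame indexed by gene symbol with one column per model
    (``lasso``, ``svm_linear``, ``random_forest``, ``neural_net``, ``gbm``,
    ``decision_tree``) plus the published ``total`` column.
    """
    path = resources.files("dilimark.data").joinpath("reference_weights.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col="gene")
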