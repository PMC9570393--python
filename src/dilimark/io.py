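"""Readers and writers for the pipeline's on-disk formats.

All artifacts are plain text: expression and fraction matrices as TSV, sample
metadata as TSV, splits/truth/summaries as JSON.  Every writer's output is
re-readable by the matching reader (round-trip property).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CellFractionMatrix, ExpressionMatrix, SampleSplit
from .simdata import SimTruth


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV (gene-id first column, sample-id header) plus
    a metadata TSV (columns: sample, group, batch)."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in {expr_path}: {dupes}")
    non_numeric = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric expression value {bad.iloc[0]!r} at gene "
                    f"{bad.index[0]!r}, sample {col!r}"
                )
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values=values.astype(float), sample_meta=meta)


def write_expression(matrix: ExpressionMatrix, expr_path, meta_path) -> None:
    matrix.values.rename_axis("gene").to_csv(expr_path, sep="\t")
    matrix.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_fractions(path) -> CellFractionMatrix:
    return CellFractionMatrix(values=pd.read_csv(path, sep="\t", index_col=0))


def write_fractions(fractions: CellFractionMatrix, path) -> None:
    fractions.values.rename_axis("sample").to_csv(path, sep="\t")


def read_split(path) -> SampleSplit:
    with open(path) as fh:
        payload = json.load(fh)
    return SampleSplit(
        train_ids=payload["train"],
        test_ids=payload["test"],
        ratio=payload.get("ratio", 0.8),
        seed=payload.get("seed", 234),
    )


def write_split(split: SampleSplit, path) -> None:
    payload = {
        "train": list(split.train_ids),
        "test": list(split.test_ids),
        "ratio": split.ratio,
        "seed": split.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "de_gene_ids": truth.de_gene_ids,
        "true_logfc": truth.true_logfc,
        "fraction_gene_links": [
            {"gene": g, "cell_type": c, "strength": s}
            for (g, c), s in truth.fraction_gene_links.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        de_gene_ids=payload["de_gene_ids"],
        true_logfc=payload["true_logfc"],
        fraction_gene_links={
            (d["gene"], d["cell_type"]): d["strength"]
            for d in payload["fraction_gene_links"]
        },
    )


def write_deg_table(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"logfc": "logFC", "t_stat": "t", "p_value": "p", "fdr": "FDR"})
    out.rename_axis("gene").to_csv(path, sep="\t")


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    return table.rename(columns={"logFC": "logfc", "t": "t_stat", "p": "p_value", "FDR": "fdr"})


def write_json(payload: dict, path) -> None:
    def _default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default) + "\n")
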