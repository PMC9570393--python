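"""End-to-end pipeline driver.

Stages: quantile normalization -> batch adjustment -> stratified 80:20 split
-> moderated-t differential expression with the three-criterion filter ->
six-model ensemble fit on the DEG features -> normalized overall-weight
aggregation and threshold selection -> per-gene ROC/AUC and test-set group
tests (-> immune-fraction correlation and gene-set enrichment when those
inputs are supplied).  Every stage's artifact is written to the output
directory and a JSON summary ties the run together; identical config and seed
reproduce the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .containers import CASE, CONTROL, CellFractionMatrix, ExpressionMatrix
from .diffexpr import DegCriteria, filter_degs, moderated_t
from .ensemble import ALGORITHM_LABELS, ModelSpec, fit_all_models
from .enrichment import GeneSetCollection, enrich
from .evaluate import auc_by_gene, group_test, immune_correlation
from .preprocess import adjust_batches, quantile_normalize, split_samples
from .weighting import normalize_importances, select_genes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    out_dir: str | Path = "dilimark_out"
    expr_path: str | Path | None = None
    meta_path: str | Path | None = None
    fractions_path: str | Path | None = None
    gmt_path: str | Path | None = None
    split_ratio: float = 0.8
    seed: int = 234
    criteria: DegCriteria = field(default_factory=DegCriteria)
    weight_threshold: float = 3.0
    model_overrides: dict[str, ModelSpec] = field(default_factory=dict)
    n_perm: int = 999


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    fractions: CellFractionMatrix | None = None,
) -> dict:
    """Execute every stage and return (and write) the summary report.

    ``matrix``/``fractions`` may be passed in memory; otherwise they are read
    from the configured paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if matrix is None:
        if config.expr_path is None or config.meta_path is None:
            raise ValueError("either an in-memory matrix or expr/meta paths are required")
        matrix = io.read_expression(config.expr_path, config.meta_path)
    if fractions is None and config.fractions_path is not None:
        fractions = io.read_fractions(config.fractions_path)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    logger.info("input: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    normalized = _stage("quantile_normalize", quantile_normalize, matrix)
    adjusted = _stage("adjust_batches", adjust_batches, normalized)
    io.write_expression(
        adjusted, out_dir / "expression_normalized.tsv", out_dir / "sample_meta.tsv"
    )

    split = _stage("split_samples", split_samples, adjusted, config.split_ratio, config.seed)
    io.write_split(split, out_dir / "split.json")
    logger.info("split: %d train / %d test", len(split.train_ids), len(split.test_ids))

    deg_records = _stage("moderated_t", moderated_t, adjusted, split)
    degs = _stage("filter_degs", filter_degs, deg_records, config.criteria)
    io.write_deg_table(deg_records, out_dir / "deg_all.tsv")
    io.write_deg_table(degs, out_dir / "deg_passing.tsv")
    logger.info("DEGs passing filter: %d of %d genes", len(degs), len(deg_records))
    if degs.empty:
        summary = {
            "n_samples": matrix.n_samples,
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
            "n_degs": 0,
            "selected_genes": [],
            "note": "no genes passed the differential-expression filter",
        }
        io.write_json(summary, out_dir / "summary.json")
        return summary

    features = degs.index.tolist()
    vectors = _stage(
        "fit_models",
        fit_all_models,
        adjusted,
        split,
        features,
        seed=config.seed,
        overrides=config.model_overrides,
    )
    for v in vectors:
        v.raw.rename("raw_importance").rename_axis("gene").to_csv(
            out_dir / f"importance_{v.model}.tsv", sep="\t"
        )
        logger.info(
            "%s: train error %.3f, test error %.3f, hyperparameters %s",
            v.model,
            v.train_error,
            v.test_error,
            v.hyperparameters,
        )

    table = _stage("normalize_importances", normalize_importances, vectors)
    table.threshold = config.weight_threshold
    weight_out = table.normalized.copy()
    weight_out["total"] = table.total
    weight_out.sort_values("total", ascending=False).rename(
        columns=ALGORITHM_LABELS
    ).rename_axis("gene").to_csv(out_dir / "weight_table.tsv", sep="\t")

    selected = _stage("select_genes", select_genes, table, config.weight_threshold)
    io.write_json(
        {"threshold": config.weight_threshold, "selected": selected},
        out_dir / "selected_genes.json",
    )
    logger.info("selected %d genes at overall weight > %s: %s",
                len(selected), config.weight_threshold, selected)

    auc_results = _stage("auc", auc_by_gene, adjusted, split, selected) if selected else []
    pd.DataFrame(
        [{"gene": r.gene, "cohort": r.cohort, "auc": r.auc} for r in auc_results]
    ).to_csv(out_dir / "auc.tsv", sep="\t", index=False)

    test_mat = adjusted.subset_samples(split.test_ids)
    test_groups = test_mat.groups()
    group_tests = []
    for gene in selected:
        expr = test_mat.values.loc[gene]
        res = _stage(
            "group_test",
            group_test,
            expr[test_groups == CASE].to_numpy(),
            expr[test_groups == CONTROL].to_numpy(),
            gene,
        )
        group_tests.append(res)

    summary: dict = {
        "n_samples": matrix.n_samples,
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "n_degs": len(degs),
        "deg_genes": features,
        "model_errors": {
            v.model: {"train": v.train_error, "test": v.test_error} for v in vectors
        },
        "model_hyperparameters": {v.model: v.hyperparameters for v in vectors},
        "weight_threshold": config.weight_threshold,
        "selected_genes": selected,
        "auc": [{"gene": r.gene, "cohort": r.cohort, "auc": r.auc} for r in auc_results],
        "test_group_tests": [dataclasses.asdict(r) for r in group_tests],
    }

    if fractions is not None and selected:
        corr = _stage("immune_correlation", immune_correlation, adjusted, fractions, selected)
        corr.to_csv(out_dir / "immune_correlation.tsv", sep="\t", index=False)
        summary["n_significant_immune_pairs"] = int((corr["p_value"] < 0.05).sum())

    if config.gmt_path is not None:
        ranked = deg_records.sort_values("t_stat", ascending=False)
        collection = GeneSetCollection.from_gmt(config.gmt_path, ranked.index.tolist())
        enr = _stage(
            "enrichment",
            enrich,
            collection,
            set(features),
            ranked.index.tolist(),
            ranked["t_stat"].to_numpy(),
            n_perm=config.n_perm,
            seed=config.seed,
        )
        enr.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        summary["n_enriched_sets"] = int((enr["ora_p"] < 0.05).sum())

    io.write_json(summary, out_dir / "summary.json")
    return summary
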