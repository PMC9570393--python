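"""Synthetic microarray cohort generator.

Emulates a multi-study DILI case/control cohort on the log2 scale: a Gaussian
baseline per gene, an additive per-(batch, gene) offset, a planted upregulation
in cases for a small set of marker genes, and i.i.d. observation noise.  The
defaults mirror the cohort structure this pipeline targets: 103 DILI cases and
29 controls pooled from six microarray batches, a few thousand genes, and a
handful of upregulated markers with log2 fold changes between 1 and 2 — one of
them clearly dominant, the way a single stress-response gene tends to dominate
every model's importance ranking in practice.

A companion generator produces per-sample immune cell-type fractions on the
22-type panel, with a few planted monotone gene-fraction associations so that
downstream correlation analysis has known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CellFractionMatrix, ExpressionMatrix

#: the 22 immune cell types of the standard deconvolution panel
IMMUNE_CELL_TYPES = [
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
]


def _default_logfc() -> list[float]:
    # one dominant marker at 2.0, the rest graded over [1.0, 1.5]
    return [2.0] + list(np.linspace(1.0, 1.5, 19))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    All expression-scale parameters are in log2 units.  ``logfc_values`` holds
    one planted effect size per differentially expressed gene (cases minus
    controls; positive = upregulated in DILI).
    """

    n_case: int = 103
    n_control: int = 29
    n_genes: int = 2000
    n_de: int = 20
    logfc_values: list[float] = field(default_factory=_default_logfc)
    n_batches: int = 6
    batch_shift_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    n_cell_types: int = 22
    n_fraction_links: int = 4
    link_strength: float = 1.0
    seed: int = 234

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes", "n_batches", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_de < 0 or self.n_de > self.n_genes:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_genes")
        if len(self.logfc_values) != self.n_de:
            raise ValueError(
                f"logfc_values has {len(self.logfc_values)} entries but n_de={self.n_de}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if self.n_fraction_links > self.n_de:
            raise ValueError("n_fraction_links cannot exceed n_de")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    de_gene_ids: list[str]
    true_logfc: dict[str, float]
    fraction_gene_links: dict[tuple[str, str], float]


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw a synthetic log2 expression matrix plus its ground truth.

    Model per gene g, sample j in batch b(j):
        x[g, j] = baseline[g] + batch_offset[b(j), g]
                  + logfc[g] * 1{j is a case} + eps,  eps ~ N(0, noise_sd^2)

    Cases occupy the first ``n_case`` columns; batches are assigned
    round-robin over samples.  The first ``n_de`` genes carry the planted
    effects.  Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_case + config.n_control

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    groups = [CASE] * config.n_case + [CONTROL] * config.n_control
    batches = [f"batch{j % config.n_batches}" for j in range(n_samples)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    batch_offsets = rng.normal(
        0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes)
    )
    if config.n_batches == 1:
        batch_offsets[:] = 0.0

    logfc = np.zeros(config.n_genes)
    logfc[: config.n_de] = np.asarray(config.logfc_values, dtype=float)
    is_case = np.array([g == CASE for g in groups], dtype=float)

    values = (
        baseline[:, None]
        + batch_offsets[[j % config.n_batches for j in range(n_samples)], :].T
        + logfc[:, None] * is_case[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    )

    matrix = ExpressionMatrix(
        values=pd.DataFrame(
            values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids
        ),
        sample_meta=pd.DataFrame(
            {"group": groups, "batch": batches}, index=pd.Index(sample_ids, name="sample")
        ),
    )

    de_gene_ids = gene_ids[: config.n_de]
    links: dict[tuple[str, str], float] = {}
    for k in range(config.n_fraction_links):
        links[(de_gene_ids[k], IMMUNE_CELL_TYPES[k % len(IMMUNE_CELL_TYPES)])] = (
            config.link_strength
        )
    truth = SimTruth(
        de_gene_ids=de_gene_ids,
        true_logfc={g: float(f) for g, f in zip(de_gene_ids, logfc[: config.n_de])},
        fraction_gene_links=links,
    )
    return matrix, truth


def simulate_cell_fractions(
    matrix: ExpressionMatrix,
    truth: SimTruth,
    seed: int,
    n_cell_types: int = 22,
    concentration: float = 5.0,
) -> CellFractionMatrix:
    """Draw per-sample immune fractions with planted gene associations.

    Fractions are Dirichlet draws on the simplex; for each planted
    (gene, cell type) link the corresponding Dirichlet concentration is
    scaled by ``exp(strength * z)`` where ``z`` is the gene's standardized
    expression in that sample, making the fraction a noisy monotone function
    of expression (known positive Spearman sign).
    """
    if matrix.n_samples < 1:
        raise ValueError("matrix must contain at least one sample")
    rng = np.random.default_rng(seed)
    cell_types = IMMUNE_CELL_TYPES[:n_cell_types]
    if n_cell_types > len(IMMUNE_CELL_TYPES):
        cell_types = cell_types + [
            f"cell_type_{i}" for i in range(len(IMMUNE_CELL_TYPES), n_cell_types)
        ]

    alpha = np.full((matrix.n_samples, n_cell_types), concentration)
    for (gene, cell), strength in truth.fraction_gene_links.items():
        if gene not in matrix.values.index or cell not in cell_types:
            continue
        expr = matrix.values.loc[gene].to_numpy(dtype=float)
        sd = expr.std()
        z = (expr - expr.mean()) / sd if sd > 0 else np.zeros_like(expr)
        alpha[:, cell_types.index(cell)] *= np.exp(strength * z)

    draws = np.vstack([rng.dirichlet(alpha[j]) for j in range(matrix.n_samples)])
    return CellFractionMatrix(
        values=pd.DataFrame(
            draws, index=pd.Index(matrix.sample_ids, name="sample"), columns=cell_types
        )
    )
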