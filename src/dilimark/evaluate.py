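"""Diagnostic evaluation of selected marker genes.

Per-gene discrimination is measured by the AUC computed through the
Mann–Whitney pair-counting identity (the probability that a random case
outscores a random control, with half credit for ties) — exact and tie-robust,
with the ROC staircase computed separately for output.  Group differences on
the test set follow a normality-gated rule: Welch's t-test when both groups
pass Shapiro–Wilk at alpha = 0.05, otherwise the two-sided Wilcoxon rank-sum
test.  Associations with immune cell-type fractions use Spearman's rank
correlation (Pearson on mid-ranks), with a t approximation for n > 10 and an
exact permutation p-value for n <= 10.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE, CONTROL, CellFractionMatrix, ExpressionMatrix, SampleSplit
from .diffexpr import bh_fdr

NORMALITY_ALPHA = 0.05


@dataclass
class AucResult:
    gene: str
    cohort: str  # "train" or "test"
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroupTestResult:
    gene: str
    statistic: float
    p_value: float
    test_used: str  # "t" or "wilcoxon"
    normality_p: float


def auc(scores_case, scores_control) -> float:
    """AUC by Mann–Whitney pair counting.

    (# pairs with case > control + 0.5 * ties) / (n_case * n_control);
    higher scores in cases give AUC > 0.5.
    """
    case = np.asarray(scores_case, dtype=float)
    ctrl = np.asarray(scores_control, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both score groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * ctrl.size))


def roc_points(scores_case, scores_control) -> list[tuple[float, float]]:
    """ROC staircase from (0,0) to (1,1), thresholds descending."""
    case = np.asarray(scores_case, dtype=float)
    ctrl = np.asarray(scores_control, dtype=float)
    scores = np.concatenate([case, ctrl])
    labels = np.concatenate([np.ones(case.size), np.zeros(ctrl.size)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(1 - labels)
    # collapse tied thresholds to their last index
    keep = np.r_[scores[1:] != scores[:-1], True]
    tpr = np.r_[0.0, tps[keep] / case.size]
    fpr = np.r_[0.0, fps[keep] / ctrl.size]
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc_by_gene(
    matrix: ExpressionMatrix, split: SampleSplit, genes: list[str]
) -> list[AucResult]:
    """Per-gene AUC on the train and test cohorts, using expression as score."""
    results = []
    for cohort, ids in (("train", split.train_ids), ("test", split.test_ids)):
        sub = matrix.subset_samples(ids)
        grp = sub.groups()
        for gene in genes:
            expr = sub.values.loc[gene]
            case = expr[grp == CASE].to_numpy()
            ctrl = expr[grp == CONTROL].to_numpy()
            results.append(
                AucResult(
                    gene=gene,
                    cohort=cohort,
                    auc=auc(case, ctrl),
                    roc_points=roc_points(case, ctrl),
                )
            )
    return results


def group_test(
    values_case, values_control, gene: str = "", force: str | None = None
) -> GroupTestResult:
    """Normality-gated two-sample test (Welch t or Wilcoxon rank-sum).

    ``force`` overrides the Shapiro–Wilk gate with ``"t"`` or ``"wilcoxon"``.
    """
    case = np.asarray(values_case, dtype=float)
    ctrl = np.asarray(values_control, dtype=float)
    if case.size < 3 or ctrl.size < 3:
        raise ValueError("need >= 3 values per group for the normality check")

    combined = np.concatenate([case, ctrl])
    if np.ptp(combined) == 0:
        return GroupTestResult(gene=gene, statistic=0.0, p_value=1.0, test_used="wilcoxon", normality_p=0.0)

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # constant values: treat as non-Gaussian
        return float(stats.shapiro(x).pvalue)

    p_case, p_ctrl = _shapiro_p(case), _shapiro_p(ctrl)
    normality_p = min(p_case, p_ctrl)
    gaussian = p_case >= NORMALITY_ALPHA and p_ctrl >= NORMALITY_ALPHA
    if force is not None:
        if force not in ("t", "wilcoxon"):
            raise ValueError(f"force must be 't' or 'wilcoxon', got {force!r}")
        gaussian = force == "t"
    if gaussian:
        res = stats.ttest_ind(case, ctrl, equal_var=False)
        return GroupTestResult(
            gene=gene,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            test_used="t",
            normality_p=normality_p,
        )
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method="auto")
    return GroupTestResult(
        gene=gene,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_used="wilcoxon",
        normality_p=normality_p,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) with a two-sided p-value.

    p uses the t approximation for n > 10 and full permutation enumeration
    for n <= 10 (exact under the null of exchangeable ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0, 1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n > 10:
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
        return rho, min(p, 1.0)

    # exact permutation: enumerate all n! rank assignments
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    observed = abs(rx_c @ ry_c)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        if abs(rx_c @ ry_c[list(perm)]) >= observed - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def immune_correlation(
    matrix: ExpressionMatrix, fractions: CellFractionMatrix, genes: list[str]
) -> pd.DataFrame:
    """Spearman correlation of each gene with each immune cell-type fraction.

    Returns a tidy DataFrame (gene, cell_type, rho, p_value, fdr); the BH
    adjustment spans all gene x cell-type pairs and is reported alongside the
    raw p-values.
    """
    shared = [s for s in matrix.sample_ids if s in set(fractions.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    rows = []
    for gene in genes:
        expr = matrix.values.loc[gene, shared].to_numpy(dtype=float)
        for cell in fractions.cell_types:
            frac = fractions.values.loc[shared, cell].to_numpy(dtype=float)
            rho, p = spearman(expr, frac)
            rows.append({"gene": gene, "cell_type": cell, "rho": rho, "p_value": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out
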