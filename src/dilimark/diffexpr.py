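"""Differential expression with an empirical-Bayes moderated t-statistic.

Per gene the model is a two-group comparison on log2 expression: the log fold
change is the case-group mean minus the control-group mean, and the per-gene
residual variance s²_g (d_g degrees of freedom) is shrunk toward a prior
variance s0² with prior degrees of freedom d0,

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),

which stabilizes the t-statistic when per-group sample sizes are small.  The
prior (d0, s0²) is fitted by moment matching on the log-variance scale: if
s²_g ~ s0²·F(d_g, d0), then log s²_g has mean and variance expressible through
digamma/trigamma functions of d_g/2 and d0/2, so d0 is recovered by inverting
the trigamma function on the excess variance of log s²_g.

Genes are declared differentially expressed by the three-criterion filter
|logFC| > 0.8, Benjamini–Hochberg FDR < 0.05, and raw p < 0.05 (the raw-p
criterion is implied by the FDR one but applied literally).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CASE, CONTROL, ExpressionMatrix, SampleSplit

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["logfc", "t_stat", "p_value", "fdr", "passes"]


@dataclass
class DegCriteria:
    """Thresholds of the differential-expression filter (strict inequalities)."""

    logfc_threshold: float = 0.8
    fdr_threshold: float = 0.05
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.logfc_threshold <= 0:
            raise ValueError("logfc_threshold must be > 0")
        for name in ("fdr_threshold", "p_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the prior (d0, s0²) to the observed residual variances.

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the observed spread of
    log s² is no larger than the sampling noise alone (complete shrinkage).
    Raises ``ValueError`` when every variance is zero.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all per-gene variances are zero: degenerate input")
    z = np.log(s2[ok])
    z_mean = float(z.mean())
    z_var = float(z.var(ddof=1)) if z.size > 1 else 0.0
    half_d = df / 2.0
    base = float(special.digamma(half_d)) - math.log(half_d)
    excess = z_var - float(special.polygamma(1, half_d))
    if excess <= 0:
        return math.inf, math.exp(z_mean - base)
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(z_mean - base + float(special.digamma(half_d0)) - math.log(half_d0))
    if not (math.isfinite(d0) and math.isfinite(s0_sq) and d0 > 0 and s0_sq > 0):
        raise FloatingPointError("variance prior estimation produced non-finite values")
    return d0, s0_sq


def moderated_t(
    matrix: ExpressionMatrix,
    train: SampleSplit | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test, cases vs controls.

    Restricted to the training samples when ``train`` is given.  Returns a
    DataFrame indexed by gene with columns ``logfc``, ``t_stat``, ``p_value``,
    ``fdr`` (Benjamini–Hochberg), and ``passes`` (initialized False; set by
    :func:`filter_degs`).

    ``d0_override=0`` disables moderation and recovers the ordinary pooled
    two-sample t-test exactly.
    """
    sub = matrix.subset_samples(train.train_ids) if train is not None else matrix
    groups = sub.groups()
    case_cols = (groups == CASE).to_numpy()
    ctrl_cols = (groups == CONTROL).to_numpy()
    n1, n2 = int(case_cols.sum()), int(ctrl_cols.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {n1} cases / {n2} controls")

    arr = sub.values.to_numpy(dtype=float)
    case = arr[:, case_cols]
    ctrl = arr[:, ctrl_cols]
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)

    df_resid = n1 + n2 - 2
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 0.0
        if d0 == 0 and not (s2 > 0).any():
            raise ValueError("all per-gene variances are zero: degenerate input")
    else:
        try:
            d0, s0_sq = fit_variance_prior(s2, df_resid)
        except FloatingPointError as exc:  # pragma: no cover - defensive path
            logger.warning("variance prior estimation failed (%s); using ordinary t", exc)
            d0, s0_sq = 0.0, 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_stat = np.divide(logfc, se, out=np.zeros_like(logfc), where=se > 0)
    zero_se = (se == 0) & (logfc != 0)
    t_stat[zero_se] = np.sign(logfc[zero_se]) * np.inf
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p_value = np.clip(p_value, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "logfc": logfc,
            "t_stat": t_stat,
            "p_value": p_value,
            "fdr": bh_fdr(p_value),
            "passes": False,
        },
        index=sub.values.index.rename("gene"),
    )
    return table


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, where p_(1..m)
    are the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def filter_degs(records: pd.DataFrame, criteria: DegCriteria | None = None) -> pd.DataFrame:
    """Apply the three-criterion filter and return passing genes.

    A gene passes iff |logFC| > logfc_threshold AND fdr < fdr_threshold AND
    p < p_threshold (all strict).  The returned table contains only passing
    genes, ordered by |t| descending; the input table gains an updated
    ``passes`` column as a side effect of the returned copy.
    """
    criteria = criteria or DegCriteria()
    records = records.copy()
    records["passes"] = (
        (records["logfc"].abs() > criteria.logfc_threshold)
        & (records["fdr"] < criteria.fdr_threshold)
        & (records["p_value"] < criteria.p_threshold)
    )
    out = records[records["passes"]].copy()
    out = out.reindex(out["t_stat"].abs().sort_values(ascending=False).index)
    return out
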