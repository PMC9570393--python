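"""Normalization, batch adjustment, and the stratified train/test split.

Multi-study microarray cohorts need two corrections before any per-gene
statistic is meaningful: quantile normalization, which forces every sample to
share the same empirical intensity distribution, and batch adjustment, which
removes study-level location/scale shifts gene by gene.  The split is
stratified by group so the heavy case/control imbalance (roughly 80:20) is
preserved in both halves.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, SampleSplit

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common rank-mean distribution.

    Each column is sorted, values are averaged across columns at each rank,
    and the rank means are written back in each column's original order.
    Tied values within a column receive the mean of the rank means they span
    (mid-rank interpolation, the standard dialect).

    Idempotent: a second application changes nothing.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        idx = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"NaN/Inf in expression at gene {matrix.gene_ids[idx[0]]!r}, "
            f"sample {matrix.sample_ids[idx[1]]!r}"
        )
    n_genes, n_samples = arr.shape
    rank_means = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    grid = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(arr[:, j], method="average")
        # fractional (tied) ranks interpolate linearly between rank means
        out[:, j] = np.interp(ranks, grid, rank_means)

    return matrix.with_values(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def adjust_batches(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove per-batch location/scale shifts gene by gene.

    For every gene, each batch's values are standardized with the batch's own
    mean and standard deviation, then rescaled to the gene's pooled mean and
    pooled standard deviation.  A batch with zero within-batch variance for a
    gene is centred only (scale step skipped, with a warning).  A single-batch
    matrix is returned unchanged.
    """
    batches = matrix.batches()
    labels = batches.unique()
    if len(labels) < 2:
        return matrix

    counts = batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(
            f"batch adjustment needs >=2 samples per batch; too small: {list(small.index)}"
        )

    arr = matrix.values.to_numpy(dtype=float)
    pooled_mean = arr.mean(axis=1, keepdims=True)
    pooled_sd = arr.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(arr)
    n_zero_var = 0
    for label in labels:
        cols = (batches == label).to_numpy()
        block = arr[:, cols]
        b_mean = block.mean(axis=1, keepdims=True)
        b_sd = block.std(axis=1, ddof=1, keepdims=True)
        zero = (b_sd[:, 0] == 0) | (pooled_sd[:, 0] == 0)
        n_zero_var += int(zero.sum())
        scale = np.where(zero[:, None], 1.0, pooled_sd / np.where(b_sd == 0, 1.0, b_sd))
        out[:, cols] = (block - b_mean) * scale + pooled_mean
    if n_zero_var:
        logger.warning(
            "adjust_batches: %d (gene, batch) blocks had zero variance; scale step skipped",
            n_zero_var,
        )
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    )


def split_samples(
    matrix: ExpressionMatrix, ratio: float = 0.8, seed: int = 234
) -> SampleSplit:
    """Seeded stratified train/test split of the samples.

    Within each group, ``floor(ratio * group size)`` samples go to the
    training set and the remainder to the test set, so a 103-case/29-control
    cohort at ratio 0.8 yields 105 training and 27 test samples in total.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    groups = matrix.groups()
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for label in sorted(groups.unique()):
        ids = np.array(groups.index[groups == label])
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        perm = rng.permutation(ids)
        n_train = int(np.floor(ratio * len(ids)))
        train_ids.extend(perm[:n_train].tolist())
        test_ids.extend(perm[n_train:].tolist())
    # restore matrix column order for reproducible downstream indexing
    order = {s: i for i, s in enumerate(matrix.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return SampleSplit(train_ids=train_ids, test_ids=test_ids, ratio=ratio, seed=seed)
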