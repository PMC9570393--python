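"""AUC pair counting, ROC staircase, group tests, Spearman correlation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_matrix
from dilimark import CellFractionMatrix, auc, group_test, immune_correlation, spearman
from dilimark.evaluate import roc_points

import pandas as pd

scores = st.lists(
    st.integers(min_value=-5, max_value=5), min_size=1, max_size=12
)  # integer scores force plenty of ties


def auc_bruteforce(case, ctrl):
    wins = sum(1.0 if c > k else 0.5 if c == k else 0.0 for c in case for k in ctrl)
    return wins / (len(case) * len(ctrl))


class TestAuc:
    def test_hand_examples(self):
        assert auc([3, 5], [1, 4]) == pytest.approx(0.75)
        assert auc([10, 11], [1, 2]) == 1.0
        assert auc([1, 1, 1], [1, 1]) == 0.5

    @given(scores, scores)
    @settings(max_examples=300, deadline=None)
    def test_matches_pair_counting_oracle(self, case, ctrl):
        assert auc(case, ctrl) == pytest.approx(auc_bruteforce(case, ctrl), abs=1e-12)

    @given(scores, scores)
    @settings(max_examples=100, deadline=None)
    def test_complement_symmetry(self, case, ctrl):
        assert auc(case, ctrl) + auc(ctrl, case) == pytest.approx(1.0, abs=1e-12)

    @given(scores, scores)
    @settings(max_examples=100, deadline=None)
    def test_equals_trapezoid_of_roc(self, case, ctrl):
        pts = roc_points(case, ctrl)
        fpr, tpr = np.array([p[0] for p in pts]), np.array([p[1] for p in pts])
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        area = np.trapezoid(tpr, fpr)
        assert auc(case, ctrl) == pytest.approx(area, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestGroupTest:
    def test_identical_groups_p_one(self):
        res = group_test([1.0] * 5, [1.0] * 5)
        assert res.p_value == 1.0
        assert res.test_used == "wilcoxon"

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        case = rng.normal(10.0, 1.0, 20)
        ctrl = rng.normal(0.0, 1.0, 20)
        res = group_test(case, ctrl)
        assert res.p_value < 1e-6

    def test_gaussian_branch_uses_welch_t(self):
        rng = np.random.default_rng(2)
        case, ctrl = rng.normal(1, 1, 30), rng.normal(0, 2, 25)
        res = group_test(case, ctrl)
        assert res.test_used == "t"
        expected = stats.ttest_ind(case, ctrl, equal_var=False)
        assert res.statistic == pytest.approx(float(expected.statistic))
        assert res.p_value == pytest.approx(float(expected.pvalue))

    def test_non_gaussian_branch_uses_ranksum(self):
        rng = np.random.default_rng(2)
        case = np.exp(rng.normal(0, 2, 40))  # heavily skewed
        ctrl = np.exp(rng.normal(1, 2, 40))
        res = group_test(case, ctrl)
        assert res.test_used == "wilcoxon"

    def test_exact_ranksum_example(self):
        # all 20 assignments of 6 values to groups of 3: U=0 in one of each
        # tail -> two-sided exact p = 2/20
        res = group_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], force="wilcoxon")
        assert res.test_used == "wilcoxon"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            group_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(20, dtype=float)
        assert spearman(x, np.exp(x / 3))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_example_with_exact_p(self):
        rho, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)  # 1 - 6*4/(5*24)
        assert p == pytest.approx(16 / 120, abs=1e-12)  # full 5! enumeration

    @pytest.mark.parametrize("seed", range(5))
    def test_rho_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        rho, p = spearman(x, y)
        expected = stats.spearmanr(x, y)
        assert rho == pytest.approx(float(expected.statistic), abs=1e-12)
        assert p == pytest.approx(float(expected.pvalue), rel=1e-6)

    def test_rho_is_pearson_on_midranks(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, size=25).astype(float)  # ties
        y = rng.integers(0, 5, size=25).astype(float)
        rho, _ = spearman(x, y)
        pearson_on_ranks = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(pearson_on_ranks, abs=1e-12)

    def test_exact_permutation_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, p = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        obs = abs(rxc @ ryc)
        count = sum(
            abs(rxc @ ryc[list(perm)]) >= obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(count / 720, abs=1e-12)


class TestImmuneCorrelation:
    def test_planted_monotone_link(self):
        rng = np.random.default_rng(3)
        n = 40
        expr = rng.normal(7, 1, size=(2, n))
        matrix = make_matrix(expr, groups=["DILI"] * 20 + ["control"] * 20)
        # cell c0 fraction strictly increasing in gene g0 expression
        ranks = np.argsort(np.argsort(expr[0]))
        c0 = np.sort(rng.uniform(0.1, 0.6, size=n))[ranks]
        base = np.column_stack([c0, (1 - c0) / 2, (1 - c0) / 2])
        fractions = CellFractionMatrix(
            values=pd.DataFrame(base, index=matrix.sample_ids, columns=["c0", "c1", "c2"])
        )
        out = immune_correlation(matrix, fractions, ["g0"])
        row = out[(out.gene == "g0") & (out.cell_type == "c0")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert set(out.columns) == {"gene", "cell_type", "rho", "p_value", "fdr"}
        assert len(out) == 3

    def test_too_few_shared_samples_rejected(self):
        matrix = make_matrix(np.zeros((2, 6)))
        fractions = CellFractionMatrix(
            values=pd.DataFrame(
                np.full((3, 2), 0.5), index=matrix.sample_ids[:3], columns=["c0", "c1"]
            )
        )
        with pytest.raises(ValueError, match="shared"):
            immune_correlation(matrix, fractions, ["g0"])
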