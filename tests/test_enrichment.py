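"""Hypergeometric ORA and the GSEA running-sum statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilimark.enrichment import GeneSetCollection, enrich, gsea_es, gsea_permutation_p, ora


def hypergeom_upper_tail_bruteforce(N, K, n, k_obs):
    """P(X >= k_obs) by direct pmf enumeration."""
    total = 0.0
    for k in range(k_obs, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
    return total


class TestOra:
    def test_hand_example(self):
        universe = {f"u{i}" for i in range(10)}
        annotation = set(list(universe)[:5])
        hits = set(list(annotation)[:4])
        assert ora(hits, annotation, universe) == pytest.approx(5 / 210, abs=1e-12)

    def test_annotation_covering_universe_forces_p_one(self):
        universe = {f"u{i}" for i in range(8)}
        assert ora(set(list(universe)[:3]), universe, universe) == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            ora({"x"}, {"a"}, {"a", "b"})

    @given(
        st.integers(min_value=1, max_value=15),
        st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_enumeration(self, n_universe, data):
        universe = [f"u{i}" for i in range(n_universe)]
        k_ann = data.draw(st.integers(min_value=1, max_value=n_universe))
        k_hit = data.draw(st.integers(min_value=1, max_value=n_universe))
        annotation = set(data.draw(st.permutations(universe))[:k_ann])
        hits = set(data.draw(st.permutations(universe))[:k_hit])
        expected = hypergeom_upper_tail_bruteforce(
            n_universe, len(annotation), len(hits), len(hits & annotation)
        )
        assert ora(hits, annotation, set(universe)) == pytest.approx(expected, abs=1e-10)


def gsea_walk_bruteforce(genes, scores, gene_set, exponent=1.0):
    """Independent step-by-step running-sum walk."""
    in_set = [g in gene_set for g in genes]
    n_miss = len(genes) - sum(in_set)
    hit_total = sum(abs(s) ** exponent for g, s in zip(genes, scores) if g in gene_set)
    running, best = 0.0, 0.0
    for g, s in zip(genes, scores):
        if g in gene_set:
            running += (abs(s) ** exponent) / hit_total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaEs:
    def test_hand_walked_example(self):
        genes = [f"gene{i}" for i in range(1, 7)]
        scores = [3, 2, 1, -1, -2, -3]
        # walk: +0.5, .25, 0, -.25, -.5, 0 -> first extreme (+0.5) wins the tie
        es = gsea_es(genes, scores, {"gene1", "gene6"})
        assert es == pytest.approx(0.5, abs=1e-12)
        assert es == pytest.approx(
            gsea_walk_bruteforce(genes, scores, {"gene1", "gene6"}), abs=1e-12
        )

    def test_top_loaded_set_positive(self):
        genes = [f"g{i}" for i in range(20)]
        scores = np.linspace(5, -5, 20)
        es = gsea_es(genes, scores, set(genes[:4]))
        # increment-only prefix maximum
        prefix = np.cumsum(np.abs(scores[:4]) / np.abs(scores[:4]).sum())
        assert es == pytest.approx(prefix.max())
        assert es > 0

    def test_whole_list_set_is_one_by_convention(self):
        genes = ["a", "b", "c"]
        assert gsea_es(genes, [3, 2, 1], {"a", "b", "c"}) == 1.0

    def test_sign_flips_when_ranking_reversed(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        gene_set = set(rng.choice(genes, size=6, replace=False))
        es_fwd = gsea_es(genes, scores, gene_set)
        es_rev = gsea_es(genes[::-1], list(scores[::-1]), gene_set)
        # reversed partial sums are the negatives of the forward ones
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_scale_invariance_of_scores(self):
        genes = [f"g{i}" for i in range(15)]
        scores = np.linspace(3, -3, 15)
        gene_set = {"g1", "g5", "g9"}
        assert gsea_es(genes, scores, gene_set) == pytest.approx(
            gsea_es(genes, scores * 7.5, gene_set), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_walk(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        genes = [f"g{i}" for i in range(n)]
        scores = rng.normal(size=n)
        size = int(rng.integers(1, n))
        gene_set = set(rng.choice(genes, size=size, replace=False))
        assert gsea_es(genes, scores, gene_set) == pytest.approx(
            gsea_walk_bruteforce(genes, scores, gene_set), abs=1e-12
        )

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            gsea_es(["a", "b"], [1, 2], {"z"})

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gsea_es(["a", "a"], [1, 2], {"a"})


class TestGseaPermutation:
    def test_top_loaded_set_is_significant(self):
        genes = [f"g{i}" for i in range(100)]
        scores = np.linspace(5, -5, 100)
        es, p = gsea_permutation_p(genes, scores, set(genes[:8]), n_perm=999, seed=1)
        assert es > 0
        assert p <= 0.01

    def test_add_one_smoothing_lower_bound(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        scores = rng.normal(size=30)
        _, p = gsea_permutation_p(genes, scores, {"g0", "g5"}, n_perm=199, seed=3)
        assert p >= 1 / 200

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            gsea_permutation_p(["a", "b"], [1, 2], {"a"}, n_perm=10)


class TestCollection:
    def test_gmt_round_trip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "SET1\tfirst set\tg1\tg2\tg3\n"
            "SET2\tsecond set\tg2\tg4\tmissing\n"
            "SET3\tdropped entirely\tabsent\n"
        )
        universe = ["g1", "g2", "g3", "g4", "g5"]
        coll = GeneSetCollection.from_gmt(gmt, universe)
        assert set(coll.sets) == {"SET1", "SET2"}
        assert coll.sets["SET2"] == ("second set", {"g2", "g4"})

    def test_enrich_produces_consistent_table(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("TOP\ttop genes\tg0\tg1\tg2\nRAND\tspread\tg3\tg9\n")
        genes = [f"g{i}" for i in range(10)]
        scores = np.linspace(4, -4, 10)
        out = enrich(
            GeneSetCollection.from_gmt(gmt, genes),
            hits=set(genes[:3]),
            ranked_genes=genes,
            scores=scores,
            n_perm=199,
            seed=5,
        )
        assert len(out) == 2
        top = out[out.set_id == "TOP"].iloc[0]
        assert top.overlap == 3
        assert top.ora_p < 0.05
        assert ((out.ora_p >= 0) & (out.ora_p <= 1)).all()
        assert (out.fdr >= out.ora_p - 1e-15).all()
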