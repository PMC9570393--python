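"""Gene-set enrichment statistics over user-supplied GMT collections.

Two complementary statistics: hypergeometric over-representation (ORA) of a
hit list against a finite gene universe, and the weighted Kolmogorov–Smirnov
running-sum enrichment score (ES) of a ranked, scored gene list, with a
gene-label permutation null for significance.  Term databases are inputs
(standard GMT files), never downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a gene universe."""

    sets: dict[str, tuple[str, set[str]]]  # set id -> (description, members)
    universe: list[str]

    @classmethod
    def from_gmt(cls, path, universe: list[str]) -> "GeneSetCollection":
        """Read a GMT file (set id, description, tab-separated members).

        Members are intersected with the universe; sets that become empty are
        dropped.
        """
        uni = set(universe)
        sets: dict[str, tuple[str, set[str]]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                set_id, description = parts[0], parts[1]
                if set_id in sets:
                    raise ValueError(f"duplicate gene-set id {set_id!r}")
                members = {g for g in parts[2:] if g} & uni
                if members:
                    sets[set_id] = (description, members)
        return cls(sets=sets, universe=list(universe))


def ora(hits: set[str], annotation: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric over-representation p-value.

    P(X >= overlap) drawing |hits| genes from a universe of size |universe|
    containing |annotation| annotated genes.
    """
    hits, annotation, universe = set(hits), set(annotation), set(universe)
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)}")
    if not annotation <= universe:
        raise ValueError(f"annotation outside universe: {sorted(annotation - universe)}")
    overlap = len(hits & annotation)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(annotation), len(hits)))


def gsea_es(ranked_genes: list[str], scores, gene_set: set[str], exponent: float = 1.0) -> float:
    """Weighted running-sum enrichment score of ``gene_set`` in a ranked list.

    Walking down the ranking, in-set genes increment the running sum by
    |score|^exponent normalized over in-set genes; out-of-set genes decrement
    by 1/(N - |set|).  The ES is the signed maximum deviation from zero.
    A set covering the whole list has ES = +1 by convention.
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(genes):
        raise ValueError("scores and ranked_genes differ in length")
    in_set = np.array([g in gene_set for g in genes])
    if not in_set.any():
        raise ValueError("gene set does not intersect the ranked list")
    if in_set.all():
        return 1.0

    weights = np.abs(scores) ** exponent
    hit_norm = weights[in_set].sum()
    if hit_norm == 0:
        # all in-set scores zero: fall back to unweighted hits
        steps_hit = np.full(int(in_set.sum()), 1.0 / in_set.sum())
    else:
        steps_hit = weights[in_set] / hit_norm
    steps = np.where(in_set, 0.0, -1.0 / (len(genes) - int(in_set.sum())))
    steps[in_set] = steps_hit
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_permutation_p(
    ranked_genes: list[str],
    scores,
    gene_set: set[str],
    n_perm: int = 999,
    seed: int = 234,
    exponent: float = 1.0,
) -> tuple[float, float]:
    """Gene-label permutation p-value for the enrichment score.

    Returns ``(es, p)`` with the add-one-smoothed estimate
    p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = list(ranked_genes)
    es = gsea_es(genes, scores, gene_set, exponent)
    set_size = len(gene_set & set(genes))
    rng = np.random.default_rng(seed)
    exceed = 0
    gene_arr = np.array(genes)
    for _ in range(n_perm):
        perm_set = set(rng.choice(gene_arr, size=set_size, replace=False))
        if abs(gsea_es(genes, scores, perm_set, exponent)) >= abs(es):
            exceed += 1
    return es, (1 + exceed) / (n_perm + 1)


def enrich(
    collection: GeneSetCollection,
    hits: set[str],
    ranked_genes: list[str],
    scores,
    n_perm: int = 999,
    seed: int = 234,
) -> pd.DataFrame:
    """ORA + GSEA over every set in a collection.

    Returns a DataFrame (set_id, description, overlap, ora_p, es, perm_p,
    fdr); the BH adjustment is over the ORA p-values.
    """
    uni = set(collection.universe)
    rows = []
    for set_id, (description, members) in collection.sets.items():
        overlap = len(set(hits) & members)
        p = ora(set(hits), members, uni)
        in_list = members & set(ranked_genes)
        if in_list:
            es, perm_p = gsea_permutation_p(
                ranked_genes, scores, members, n_perm=n_perm, seed=seed
            )
        else:
            es, perm_p = np.nan, np.nan
        rows.append(
            {
                "set_id": set_id,
                "description": description,
                "overlap": overlap,
                "ora_p": p,
                "es": es,
                "perm_p": perm_p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["ora_p"].to_numpy()) if len(out) else []
    return out
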