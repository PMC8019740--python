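"""Unweighted preranked GSEA, right-sided hypergeometric ORA with BH
correction, and the subsampling null for TF-family enrichment.

The GSEA enrichment score is the classic running sum with exponent 0:
+1/N_hit at gene-set members, -1/N_miss elsewhere, scored at the point of
maximal absolute deviation (signed). Significance comes from random
equal-size gene sets drawn from the ranked universe, so p-values are
permutation-grade rather than fgsea-exact. The subsampling null repeatedly
draws query-sized gene sets from a background pool, runs per-TF ORA with
BH correction and counts significantly enriched family TFs per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    fdr: float | None = None


@dataclass
class ORAResult:
    term_id: str
    overlap: int
    expected: float
    p_value: float
    bh_fdr: float | None = None


def _ranked_ids(ranked) -> list:
    """Accept an ordered id sequence or a (gene_id, score) frame sorted on
    demand with lexicographic tie-break for determinism."""
    if isinstance(ranked, pd.DataFrame):
        df = ranked.sort_values(["score", "gene_id"], ascending=[False, True])
        ids = list(df["gene_id"])
    else:
        ids = list(ranked)
    if len(set(ids)) != len(ids):
        raise ValueError("ranked list contains duplicate genes")
    return ids


def gsea_es(ranked, gene_set: set) -> float:
    """Unweighted enrichment score of ``gene_set`` on the ranked list."""
    ids = _ranked_ids(ranked)
    member = np.isin(np.array(ids, dtype=object), list(gene_set))
    if int(member.sum()) == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    return _es_from_member(member)


def _es_from_member(member: np.ndarray) -> float:
    # integer running sum (steps scaled by n_hit*n_miss) keeps exact-tie
    # handling stable: the first position of maximal |deviation| wins
    n_hit = int(member.sum())
    n_miss = len(member) - n_hit
    if n_miss == 0:
        return 1.0
    running = np.cumsum(np.where(member, n_miss, -n_hit))
    return float(running[int(np.argmax(np.abs(running)))]) / (n_hit * n_miss)


def gsea_significance(ranked, gene_set: set, n_perm: int = 1000,
                      seed: int = 0, set_id: str = "set") -> EnrichmentResult:
    """Permutation p-value and NES from random equal-size gene sets."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids = _ranked_ids(ranked)
    member = np.isin(np.array(ids, dtype=object), list(gene_set))
    es = _es_from_member(member)
    k, n = int(member.sum()), len(ids)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    template = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        m = template.copy()
        m[rng.choice(n, size=k, replace=False)] = True
        null[i] = _es_from_member(m)
    same = null >= 0 if es >= 0 else null < 0
    n_same = int(same.sum())
    p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
    mean_abs = float(np.abs(null[same]).mean()) if n_same else float("nan")
    nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else float("nan")
    return EnrichmentResult(set_id=set_id, es=es, nes=nes, p_value=p)


def ora_hypergeom(query: set, term: set, universe: set) -> ORAResult:
    """Right-sided hypergeometric overlap test of ``query`` against ``term``."""
    if not universe:
        raise ValueError("empty universe")
    if not term <= universe or not query <= universe:
        raise ValueError("term and query must be subsets of the universe")
    M, n, N = len(universe), len(term), len(query)
    overlap = len(query & term)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    return ORAResult(term_id="term", overlap=overlap,
                     expected=N * n / M, p_value=p)


def ora_table(query: set, terms: dict, universe: set) -> pd.DataFrame:
    """ORA over many terms with Benjamini-Hochberg correction."""
    rows = []
    for term_id in sorted(terms):
        r = ora_hypergeom(query, set(terms[term_id]) & universe, universe)
        rows.append((term_id, r.overlap, r.expected, r.p_value))
    df = pd.DataFrame(rows, columns=["term_id", "overlap", "expected", "p_value"])
    if not df.empty:
        df["bh_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def subsample_tf_null(pool: set, tf_annotation: dict, tf_family: set,
                      n_draw: int = 179, n_reps: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> np.ndarray:
    """Distribution of enriched-family-TF counts over random query draws.

    Each repetition samples ``n_draw`` genes from ``pool`` without
    replacement, tests every annotated TF for overrepresentation against
    the pool as universe, BH-corrects across TFs, and counts family TFs
    with corrected p below ``alpha``. Returns the per-draw counts.
    """
    pool_ids = np.array(sorted(pool), dtype=object)
    if len(pool_ids) < n_draw:
        raise ValueError("pool smaller than n_draw")
    tfs = sorted(tf_annotation)
    if not tfs:
        return np.zeros(n_reps, dtype=int)
    membership = np.array([[g in set(tf_annotation[tf]) for g in pool_ids]
                           for tf in tfs])
    term_sizes = membership.sum(axis=1)
    fam_mask = np.array([tf in tf_family for tf in tfs])
    M = len(pool_ids)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        idx = rng.choice(M, size=n_draw, replace=False)
        overlaps = membership[:, idx].sum(axis=1)
        p = stats.hypergeom.sf(overlaps - 1, M, term_sizes, n_draw)
        fdr = multipletests(p, method="fdr_bh")[1]
        counts[r] = int(((fdr < alpha) & fam_mask).sum())
    return counts
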