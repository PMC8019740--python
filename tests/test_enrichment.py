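"""Unweighted GSEA running sum, hypergeometric ORA and subsampling null."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from rbptargets.enrichment import (gsea_es, gsea_significance, ora_hypergeom,
                                   ora_table, subsample_tf_null)


def _naive_es(ids, gene_set):
    """Exact-fraction running-sum oracle."""
    hits = [g in gene_set for g in ids]
    nh = sum(hits)
    nm = len(ids) - nh
    run, best = Fraction(0), Fraction(0)
    for h in hits:
        run += Fraction(1, nh) if h else -Fraction(1, nm)
        if abs(run) > abs(best):
            best = run
    return float(best)


def test_extreme_single_gene_sets():
    ids = [f"g{i}" for i in range(5)]
    assert gsea_es(ids, {"g0"}) == pytest.approx(1.0)
    assert gsea_es(ids, {"g4"}) == pytest.approx(-1.0)
    assert gsea_es(ids, set(ids)) == pytest.approx(1.0)


def test_es_matches_exhaustive_oracle_for_all_subsets():
    """Every non-empty subset of an 8-gene list agrees with the oracle."""
    ids = [f"g{i}" for i in range(8)]
    for r in range(1, 9):
        for comb in itertools.combinations(ids, r):
            assert gsea_es(ids, set(comb)) == pytest.approx(
                _naive_es(ids, set(comb)), abs=1e-12)


def _extreme_multiplicity(ids, gene_set):
    """How many running-sum positions attain the maximal |deviation|."""
    hits = [g in gene_set for g in ids]
    nh = sum(hits)
    nm = len(ids) - nh
    run, vals = Fraction(0), []
    for h in hits:
        run += Fraction(1, nh) if h else -Fraction(1, nm)
        vals.append(run)
    m = max(abs(v) for v in vals)
    return sum(abs(v) == m for v in vals)


def test_es_antisymmetric_under_list_reversal():
    """Reversing the list flips the ES sign whenever the extreme deviation
    is unique (magnitude ties can legitimately keep the sign)."""
    rng = np.random.default_rng(41)
    ids = [f"g{i}" for i in range(30)]
    for _ in range(20):
        s = set(rng.choice(ids, size=6, replace=False))
        es, es_rev = gsea_es(ids, s), gsea_es(ids[::-1], s)
        assert abs(es) == pytest.approx(abs(es_rev), abs=1e-12)
        if _extreme_multiplicity(ids, s) == 1:
            assert es == pytest.approx(-es_rev, abs=1e-12)


def test_disjoint_set_rejected():
    with pytest.raises(ValueError):
        gsea_es(["a", "b"], {"z"})


def test_significance_deterministic_and_detects_top_block():
    ids = [f"g{i:04d}" for i in range(1000)]
    top = set(ids[:10])
    r1 = gsea_significance(ids, top, n_perm=1000, seed=3)
    r2 = gsea_significance(ids, top, n_perm=1000, seed=3)
    assert (r1.es, r1.nes, r1.p_value) == (r2.es, r2.nes, r2.p_value)
    assert r1.p_value <= 0.01
    assert np.sign(r1.nes) == np.sign(r1.es) == 1.0


def test_ora_closed_form_examples():
    uni = {f"g{i}" for i in range(10)}
    term = {f"g{i}" for i in range(5)}
    query = {f"g{i}" for i in range(4)}
    r = ora_hypergeom(query, term, uni)
    assert r.overlap == 4
    assert r.p_value == pytest.approx(5 / 210)
    assert ora_hypergeom({"g9"}, term, uni).p_value == pytest.approx(1.0)
    assert ora_hypergeom(query, uni, uni).p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ora_hypergeom(query, term, set())


def test_ora_matches_urn_monte_carlo():
    """Hypergeometric tail within 3 SE of a 1e5-draw urn simulation."""
    rng = np.random.default_rng(42)
    M, n, N = 60, 18, 12
    uni = [f"g{i}" for i in range(M)]
    term = set(uni[:n])
    query = set(rng.choice(uni, size=N, replace=False))
    r = ora_hypergeom(query, term, set(uni))
    draws = 100_000
    hits = np.array([len(set(rng.choice(uni, size=N, replace=False)) & term)
                     for _ in range(draws)])
    p_mc = (hits >= r.overlap).mean()
    se = np.sqrt(p_mc * (1 - p_mc) / draws)
    assert abs(r.p_value - p_mc) <= 3 * se + 1e-9


def test_ora_table_applies_bh():
    uni = {f"g{i}" for i in range(50)}
    terms = {"t1": set(list(uni)[:10]), "t2": set(list(uni)[10:20])}
    df = ora_table(set(list(uni)[:8]), terms, uni)
    assert set(df.columns) >= {"term_id", "p_value", "bh_fdr"}
    assert (df["bh_fdr"] >= df["p_value"] - 1e-12).all()


def test_subsample_null_deterministic_and_empty_annotation():
    pool = {f"g{i}" for i in range(60)}
    rng = np.random.default_rng(43)
    ann = {f"tf{i}": set(np.random.default_rng(i).choice(sorted(pool), 10,
                                                         replace=False))
           for i in range(6)}
    fam = {"tf0", "tf1"}
    c1 = subsample_tf_null(pool, ann, fam, n_draw=20, n_reps=50, seed=9)
    c2 = subsample_tf_null(pool, ann, fam, n_draw=20, n_reps=50, seed=9)
    assert np.array_equal(c1, c2) and len(c1) == 50
    zeros = subsample_tf_null(pool, {}, fam, n_draw=20, n_reps=50, seed=9)
    assert (zeros == 0).all()


def test_subsample_null_requires_large_enough_pool():
    with pytest.raises(ValueError):
        subsample_tf_null({"a", "b"}, {"tf": {"a"}}, set(), n_draw=5, n_reps=10)
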