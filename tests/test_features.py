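"""3'UTR feature annotation: ARE scanning, motif densities, m6A counts,
and Mann-Whitney group comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rbptargets.features import (are_scan, compare_groups, m6a_count,
                                 max_utr3, motif_density)
from rbptargets.models import GeneModels

from conftest import make_transcript


# ------------------------------------------------------------------ ARE scan

def _naive_are(seq):
    """Sliding-window re-implementation used as an oracle."""
    seq = seq.upper().replace("T", "U")
    n, has = 0, False
    for i in range(len(seq) - 4):
        if seq[i:i + 5] == "AUUUA":
            n += 1
            win = seq[max(0, i - 4): i + 9]
            if sum(c in "AU" for c in win) / len(win) >= 10 / 13:
                has = True
    return has, n


def test_no_pentamer_means_no_are():
    assert are_scan("GCGCGCGCGCGC") == (False, 0)


def test_overlapping_pentamers_counted():
    has, n = are_scan("UUUAUUUAUUUAU")
    assert (has, n) == (True, 2)


def test_are_scan_matches_sliding_window_oracle():
    rng = np.random.default_rng(21)
    for _ in range(40):
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 120)),
                                 p=[0.3, 0.2, 0.2, 0.3]))
        assert are_scan(seq) == _naive_are(seq)


def test_t_and_u_equivalent_and_bad_chars_rejected():
    assert are_scan("GCATTTAATTG") == are_scan("GCAUUUAAUUG")
    with pytest.raises(ValueError):
        are_scan("ACGX")


def test_planted_target_ares_exceed_null_fraction(study_bundle):
    models, seqs = study_bundle.models, study_bundle.utr3_seqs
    frac = {}
    for label in ("target_down", "stable_null"):
        genes = study_bundle.truth_genes(label)
        flags = [are_scan(seqs[models.designated_transcript(g).transcript_id])[0]
                 for g in genes]
        frac[label] = np.mean(flags)
    assert frac["target_down"] > frac["stable_null"]


# ------------------------------------------------------------------ motifs

def test_motif_density_examples():
    assert motif_density("ACGU", ["ACGU"])["ACGU"] == 1.0
    # IUPAC H = A/C/U but not G
    assert motif_density("CAUA", ["CAUH"])["CAUH"] == 1.0
    assert motif_density("CAUG", ["CAUH"])["CAUH"] == 0.0


def test_motif_density_matches_iupac_expansion_oracle():
    rng = np.random.default_rng(22)
    iupac = {"H": "ACU", "N": "ACGU", "R": "AG", "A": "A", "C": "C",
             "G": "G", "U": "U"}
    for motif in ["CAUH", "GGAC", "RNAU"]:
        expansions = {"".join(c) for c in
                      itertools.product(*[iupac[ch] for ch in motif])}
        seq = "".join(rng.choice(list("ACGU"), size=300))
        n = sum(seq[i:i + 4] in expansions for i in range(len(seq) - 3))
        assert motif_density(seq, [motif])[motif] == pytest.approx(
            n / (len(seq) - 3))


def test_motif_free_flank_halves_density():
    seq = "CAUACAUA"
    d1 = motif_density(seq, ["CAUA"])["CAUA"]
    d2 = motif_density(seq + "G" * len(seq), ["CAUA"])["CAUA"]
    assert d2 == pytest.approx(d1 * (len(seq) - 3) / (2 * len(seq) - 3))


def test_non_tetramer_motif_rejected():
    with pytest.raises(ValueError):
        motif_density("ACGUACGU", ["ACGUA"])


# ------------------------------------------------------------------ m6A

def test_m6a_count_takes_per_gene_maximum_and_skips_introns():
    t1 = make_transcript(tid="g.t1", gene="g", exons=((0, 100),), cds=(10, 70))
    t2 = make_transcript(tid="g.t2", gene="g", exons=((0, 50), (200, 300)),
                         cds=(10, 240))
    models = GeneModels.from_transcripts([t1, t2])
    # 3 sites exonic on both, 2 extra exonic only on t2, one intronic for t2
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": [20, 30, 40, 250, 260, 120],
                          "strand": "+"})
    assert m6a_count("g", sites, models) == 5
    assert m6a_count("g", sites.iloc[0:0], models) == 0


def test_m6a_count_matches_brute_force(small_bundle):
    models, sites = small_bundle.models, small_bundle.m6a
    rng = np.random.default_rng(1)
    for g in rng.choice(models.gene_ids, size=15, replace=False):
        brute = 0
        for t in models.by_gene[g]:
            n = 0
            for r in sites.itertuples():
                if r.chrom == t.chrom and any(s <= r.pos < e for s, e in t.exons):
                    n += 1
            brute = max(brute, n)
        assert m6a_count(g, sites, models) == brute


def test_max_utr3_over_isoforms():
    t1 = make_transcript(tid="g.t1", gene="g", exons=((0, 500),), cds=(10, 100))
    t2 = make_transcript(tid="g.t2", gene="g", exons=((0, 160),), cds=(10, 100))
    assert max_utr3([t1, t2]) == 400
    assert max_utr3([t2]) == 60


# ------------------------------------------------------------------ Mann-Whitney

def test_exact_p_small_sample():
    u, p = compare_groups([1, 2], [3, 4], alternative="less")
    assert p == pytest.approx(1 / 6)


def test_identical_groups_give_central_u_and_degenerate_p():
    u, p = compare_groups([5, 5, 5], [5, 5, 5])
    assert u == 4.5 and p == 1.0


def test_exact_p_matches_full_enumeration():
    """Exact one-sided p equals the rank-assignment enumeration oracle."""
    rng = np.random.default_rng(23)
    for _ in range(10):
        na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pooled = rng.permutation(np.arange(1.0, na + nb + 1))  # tie-free
        a, b = pooled[:na], pooled[na:]
        u_obs, p = compare_groups(a, b, alternative="greater")
        ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
        count = total = 0
        for comb in itertools.combinations(sorted(pooled), na):
            u = sum(ranks[v] for v in comb) - na * (na + 1) / 2
            total += 1
            if u >= u_obs:
                count += 1
        assert p == pytest.approx(count / total)


def test_large_sample_p_close_to_permutation_oracle():
    rng = np.random.default_rng(24)
    a = rng.normal(0.7, 1, 30)
    b = rng.normal(0.0, 1, 30)
    u, p = compare_groups(a, b, alternative="greater")
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata
    n_extreme = 0
    reps = 20000
    for _ in range(reps):
        perm = rng.permutation(pooled)
        ranks = rankdata(perm)
        u_p = ranks[:30].sum() - 30 * 31 / 2
        if u_p >= u:
            n_extreme += 1
    p_mc = (n_extreme + 1) / (reps + 1)
    assert p == pytest.approx(p_mc, rel=0.25, abs=0.002)


def test_p_invariant_under_monotone_transform():
    rng = np.random.default_rng(25)
    a, b = rng.lognormal(0.5, 1, 20), rng.lognormal(0, 1, 25)
    _, p1 = compare_groups(a, b)
    _, p2 = compare_groups(np.log(a), np.log(b))
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        compare_groups([], [1.0])
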