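"""Spearman tallies against the driver gene and UNP/DPP/NDP labeling."""

import math

import numpy as np
import pandas as pd
import pytest

from rbptargets.correlation import (CohortData, assign_labels, spearman_rho,
                                    tally_signs)


def _midrank(v):
    """Independent mid-rank computation (average rank for ties)."""
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


@pytest.mark.parametrize("x,y,expected", [
    ([1, 2, 3], [10, 20, 30], 1.0),
    ([1, 2, 3], [3, 2, 1], -1.0),
])
def test_monotone_vectors(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected)


def test_ties_match_brute_force_midrank_pearson():
    rng = np.random.default_rng(2)
    cases = [([1, 2, 2, 3], [2, 1, 3, 4])]
    for _ in range(25):
        n = int(rng.integers(4, 15))
        cases.append((list(rng.integers(0, 5, n)), list(rng.integers(0, 5, n))))
    for x, y in cases:
        if np.ptp(_midrank(x)) == 0 or np.ptp(_midrank(y)) == 0:
            continue
        oracle = _pearson(_midrank(x), _midrank(y))
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)


def test_constant_vector_is_flagged_undefined():
    assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


def _cohort(cid, data, rng):
    expr = pd.DataFrame(data).T  # genes x samples
    expr.columns = [f"s{i}" for i in range(expr.shape[1])]
    surv = pd.DataFrame({"sample_id": expr.columns,
                         "time": rng.uniform(1, 5, expr.shape[1]),
                         "event": 1})
    return CohortData(cohort_id=cid, expression=expr, survival=surv)


def test_tally_counts_and_degenerate_exclusion():
    rng = np.random.default_rng(3)
    cohorts = []
    for c in range(5):
        d = list(rng.normal(size=10))
        cohorts.append(_cohort(f"c{c}", {
            "DRV": d,
            "pos": [x + rng.normal(0, 0.01) for x in d],
            "neg": [-x for x in d],
            "flat": [1.0] * 10,
        }, rng))
    t = tally_signs("DRV", ["pos", "neg", "flat"], cohorts).set_index("gene_id")
    assert t.at["pos", "n_pos"] == 5 and t.at["pos", "n_neg"] == 0
    assert t.at["neg", "n_neg"] == 5
    assert t.at["flat", "n_pos"] == 0 and t.at["flat", "n_neg"] == 0


def test_sign_tally_invariant_under_monotone_transforms():
    rng = np.random.default_rng(4)
    d = rng.normal(size=12)
    g = 0.8 * d + rng.normal(0, 0.5, 12)
    base = _cohort("c", {"DRV": list(d), "g": list(g)}, rng)
    warped = _cohort("c", {"DRV": list(np.exp(d)), "g": list(g ** 3)}, rng)
    tb = tally_signs("DRV", ["g"], [base])
    tw = tally_signs("DRV", ["g"], [warped])
    assert tb.at[0, "n_pos"] == tw.at[0, "n_pos"]
    assert tb.at[0, "n_neg"] == tw.at[0, "n_neg"]


def _calls(status_by_gene):
    return pd.DataFrame({"gene_id": list(status_by_gene),
                         "status": list(status_by_gene.values()),
                         "n_experiments_significant": 6})


def _tallies(counts):
    return pd.DataFrame({"gene_id": list(counts),
                         "n_pos": [c[0] for c in counts.values()],
                         "n_neg": [c[1] for c in counts.values()]})


def test_label_assignment_thresholds():
    calls = _calls({"a": "cons_down", "b": "cons_down", "c": "cons_up",
                    "d": "cons_unchanged", "e": "inconsistent"})
    tallies = _tallies({"a": (22, 5), "b": (19, 5), "c": (3, 25),
                        "d": (0, 31), "e": (31, 0)})
    lab = assign_labels(calls, tallies).set_index("gene_id")["label"]
    assert lab.to_dict() == {"a": "DPP", "b": "unlabeled", "c": "UNP",
                             "d": "NDP", "e": "unlabeled"}


def test_labels_partition_is_disjoint(study_result):
    assert not (study_result.dpp & study_result.ndp)
    assert not (study_result.unp & study_result.ndp)
    assert not (study_result.dpp & study_result.unp)
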