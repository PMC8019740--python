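"""Per-cohort Spearman correlation against the driver gene and the
UNP/DPP/NDP label assignment.

Spearman's rho is the Pearson correlation of mid-ranks (ties receive
average ranks). A cohort contributes to a gene's sign tally only when rho
is defined there (both rank vectors have positive variance); rho exactly 0
counts to neither sign. A consistently down-regulated gene becomes a DPP
when positively correlated with the driver in at least ``min_cohorts``
cohorts, a consistently up-regulated gene a UNP with negative correlation
symmetrically, and every consistently unchanged gene is an NDP regardless
of its correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CohortData:
    """Expression matrix (genes x samples, driver row included) plus
    per-sample survival annotation for one cohort."""

    cohort_id: str
    expression: pd.DataFrame
    survival: pd.DataFrame  # sample_id, time, event

    def __post_init__(self) -> None:
        if (self.survival["time"] <= 0).any():
            raise ValueError(f"{self.cohort_id}: non-positive survival time")


def spearman_rho(x, y) -> float:
    """Spearman correlation; NaN when either rank vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _cohort_rhos(cohort: CohortData, driver: str, genes: list) -> pd.Series:
    """Spearman rho of every requested gene against the driver, vectorised
    over the cohort's expression matrix (mid-rank Pearson per row)."""
    expr = cohort.expression
    if driver not in expr.index:
        raise KeyError(f"driver {driver!r} absent from {cohort.cohort_id}")
    present = [g for g in genes if g in expr.index]
    missing = len(genes) - len(present)
    if missing:
        logger.info("%s: %d gene(s) absent, skipped", cohort.cohort_id, missing)
    rd = stats.rankdata(expr.loc[driver].to_numpy())
    rd = rd - rd.mean()
    denom_d = float(rd @ rd)
    mat = stats.rankdata(expr.loc[present].to_numpy(), axis=1)
    mat = mat - mat.mean(axis=1, keepdims=True)
    ss = (mat * mat).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mat @ rd) / np.sqrt(ss * denom_d)
    rho[(ss == 0) | (denom_d == 0)] = np.nan
    return pd.Series(rho, index=present).reindex(genes)


def tally_signs(driver: str, genes: list, cohorts: list) -> pd.DataFrame:
    """Per-gene counts of cohorts with positive / negative rho vs the driver.

    Returns one row per gene with ``n_pos``, ``n_neg`` and the per-cohort
    rho columns; undefined rhos are excluded from both counts.
    """
    genes = list(genes)
    rho = pd.DataFrame({c.cohort_id: _cohort_rhos(c, driver, genes)
                        for c in cohorts})
    out = pd.DataFrame({
        "gene_id": genes,
        "n_pos": (rho > 0).sum(axis=1).to_numpy(),
        "n_neg": (rho < 0).sum(axis=1).to_numpy(),
    })
    return pd.concat([out, rho.reset_index(drop=True)], axis=1)


def assign_labels(calls: pd.DataFrame, tallies: pd.DataFrame,
                  min_cohorts: int = 20) -> pd.DataFrame:
    """UNP/DPP/NDP labels from consistency status plus correlation tallies."""
    t = tallies.set_index("gene_id")
    labels = []
    for row in calls.itertuples():
        label = "unlabeled"
        if row.status == "cons_unchanged":
            label = "NDP"
        elif row.status in ("cons_down", "cons_up"):
            if row.gene_id not in t.index:
                raise KeyError(f"no correlation tally for {row.gene_id}")
            n_pos = int(t.at[row.gene_id, "n_pos"])
            n_neg = int(t.at[row.gene_id, "n_neg"])
            if row.status == "cons_down" and n_pos >= min_cohorts:
                label = "DPP"
            elif row.status == "cons_up" and n_neg >= min_cohorts:
                label = "UNP"
        labels.append(label)
    return pd.DataFrame({"gene_id": calls["gene_id"], "label": labels})


def label_genes(labels: pd.DataFrame, label: str) -> set:
    return set(labels.loc[labels["label"] == label, "gene_id"])
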