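"""Median-split survival analysis: log-rank test via the observed/expected
risk-table walk and the O/E hazard ratio, plus pan-cohort summaries.

At each distinct event time the expected events per group under the
hypergeometric null are accumulated; the test statistic is
``sum_g (O_g - E_g)^2 / E_g`` on one degree of freedom and the hazard
ratio is ``(O_high/E_high) / (O_low/E_low)``. Individuals censored at an
event time remain at risk for events at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HazardSummary:
    gene_id: str
    cohort_id: str
    hr: float  # NaN when a group has zero expected events
    log2_hr: float
    chi_sq: float
    p_value: float


def median_split(expr: pd.Series, ties_to: str = "low") -> pd.Series:
    """'high'/'low' group per sample by the gene's median expression.

    Samples strictly above the median are 'high'; samples exactly at the
    median go to the ``ties_to`` group (defaults to 'low').
    """
    if len(expr) < 4:
        raise ValueError("need at least 4 samples")
    if expr.nunique() == 1:
        raise ValueError("all expression values identical; no split possible")
    med = expr.median()
    if ties_to == "low":
        return pd.Series(np.where(expr > med, "high", "low"), index=expr.index)
    return pd.Series(np.where(expr >= med, "high", "low"), index=expr.index)


def logrank_hr(records: pd.DataFrame, gene_id: str = "", cohort_id: str = ""
               ) -> HazardSummary:
    """Log-rank chi-square and O/E hazard ratio for a grouped cohort.

    ``records`` needs columns time, event and group ('high'/'low').
    """
    for g in ("high", "low"):
        if not (records["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    if records["event"].sum() < 1:
        raise ValueError("no events observed")
    t = records["time"].to_numpy(dtype=float)
    ev = records["event"].to_numpy(dtype=int)
    hi = (records["group"] == "high").to_numpy()
    O = {"high": 0.0, "low": 0.0}
    E = {"high": 0.0, "low": 0.0}
    for et in np.unique(t[ev == 1]):
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        d_tot = int(((t == et) & (ev == 1)).sum())
        d_hi = int(((t == et) & (ev == 1) & hi).sum())
        n_hi = int((at_risk & hi).sum())
        O["high"] += d_hi
        O["low"] += d_tot - d_hi
        E["high"] += d_tot * n_hi / n_tot
        E["low"] += d_tot * (n_tot - n_hi) / n_tot
    chi = sum((O[g] - E[g]) ** 2 / E[g] for g in ("high", "low") if E[g] > 0)
    p = float(stats.chi2.sf(chi, df=1))
    if E["high"] > 0 and E["low"] > 0 and O["high"] > 0 and O["low"] > 0:
        hr = (O["high"] / E["high"]) / (O["low"] / E["low"])
        log2_hr = float(np.log2(hr))
    else:
        hr, log2_hr = float("nan"), float("nan")
    return HazardSummary(gene_id=gene_id, cohort_id=cohort_id, hr=hr,
                         log2_hr=log2_hr, chi_sq=float(chi), p_value=p)


def gene_cohort_hazard(cohort, gene_id: str, ties_to: str = "low") -> HazardSummary:
    """Median-split one gene's expression in one cohort and run the test."""
    expr = cohort.expression.loc[gene_id, cohort.survival["sample_id"]]
    groups = median_split(expr, ties_to=ties_to)
    rec = cohort.survival.assign(group=groups.to_numpy())
    return logrank_hr(rec, gene_id=gene_id, cohort_id=cohort.cohort_id)


def pan_cohort_summary(summaries: list) -> tuple[pd.Series, pd.DataFrame]:
    """Median log2 HR per gene across cohorts plus the per-cohort matrix.

    Cohorts with an undefined (NaN) hazard ratio are excluded from the
    median for that gene.
    """
    df = pd.DataFrame([(s.gene_id, s.cohort_id, s.log2_hr) for s in summaries],
                      columns=["gene_id", "cohort_id", "log2_hr"])
    matrix = df.pivot(index="gene_id", columns="cohort_id", values="log2_hr")
    return matrix.median(axis=1, skipna=True), matrix
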