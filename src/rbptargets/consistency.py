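"""Conserved-regulation calls from per-experiment DE tables.

A gene is consistently down-regulated when it is significant (FDR strictly
below the significance threshold) with negative log2 fold change in every
experiment, consistently up-regulated symmetrically, and consistently
unchanged when its FDR is at or above the high-confidence stability
threshold everywhere. Everything else — including genes missing from any
table — is ``inconsistent``.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_BIOTYPES = {"protein_coding", "lincRNA", "other"}
STATUSES = ("cons_up", "cons_down", "cons_unchanged", "inconsistent")


def filter_biotype(table: pd.DataFrame, allowed: set) -> pd.DataFrame:
    """Keep only records whose biotype is explicitly whitelisted.

    Biotype strings outside ``allowed`` — including unknown ones — are
    dropped; the number of dropped unknown-biotype records is logged.
    """
    keep = table["biotype"].isin(allowed)
    unknown = ~table["biotype"].isin(KNOWN_BIOTYPES | set(allowed))
    if unknown.any():
        logger.info("filter_biotype: dropped %d records with unknown biotype",
                    int(unknown.sum()))
    return table.loc[keep].copy()


def classify_consistency(tables: list, fdr_sig: float = 0.05,
                         fdr_stable: float = 0.95) -> pd.DataFrame:
    """Classify every gene seen in any table by cross-experiment consistency.

    Returns a frame with ``gene_id``, ``status`` and
    ``n_experiments_significant`` (tables where FDR < ``fdr_sig``).
    """
    if len(tables) < 2:
        raise ValueError("need at least two experiments")
    if not (0.0 < fdr_sig < fdr_stable < 1.0):
        raise ValueError("require 0 < fdr_sig < fdr_stable < 1")
    for i, t in enumerate(tables):
        dup = t["gene_id"][t["gene_id"].duplicated()]
        if not dup.empty:
            raise ValueError(
                f"gene(s) duplicated within table {i}: {sorted(set(dup))}")
    n_tables = len(tables)
    fdr = pd.concat([t.set_index("gene_id")["fdr"] for t in tables],
                    axis=1, keys=range(n_tables))
    lfc = pd.concat([t.set_index("gene_id")["log2fc"] for t in tables],
                    axis=1, keys=range(n_tables))
    present = fdr.notna().all(axis=1) & lfc.notna().all(axis=1)
    sig = fdr < fdr_sig
    n_sig = sig.sum(axis=1)
    all_down = present & (sig & (lfc < 0)).sum(axis=1).eq(n_tables)
    all_up = present & (sig & (lfc > 0)).sum(axis=1).eq(n_tables)
    all_stable = present & (fdr >= fdr_stable).sum(axis=1).eq(n_tables)
    status = pd.Series("inconsistent", index=fdr.index, dtype=object)
    status[all_down] = "cons_down"
    status[all_up] = "cons_up"
    status[all_stable] = "cons_unchanged"
    out = pd.DataFrame({"gene_id": fdr.index, "status": status.to_numpy(),
                        "n_experiments_significant": n_sig.to_numpy()})
    return out.reset_index(drop=True)


def status_genes(calls: pd.DataFrame, status: str) -> set:
    return set(calls.loc[calls["status"] == status, "gene_id"])
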