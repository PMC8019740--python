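"""Multi-database miRNA target-prediction consensus and expression filter.

A miRNA-gene pair is a putative interaction when reported by at least
``min_dbs`` distinct prediction databases. The expressed-miRNA filter keeps
miRNAs whose per-cell-line average CPM passes the threshold in at least
``min_lines`` cell lines; the comparison direction is configurable because
the selection of "expressed" miRNAs admits two textual readings (the
default keeps miRNAs at or above the CPM threshold).
"""

from __future__ import annotations

import pandas as pd


def consensus_pairs(preds: pd.DataFrame, db_names: list, min_dbs: int = 2) -> set:
    """(mirna_id, gene_id) pairs reported by >= min_dbs distinct databases."""
    unknown = set(preds["db_name"]) - set(db_names)
    if unknown:
        raise ValueError(f"unknown database name(s): {sorted(unknown)}")
    counts = (preds.drop_duplicates(["mirna_id", "gene_id", "db_name"])
              .groupby(["mirna_id", "gene_id"]).size())
    return set(counts.index[counts >= min_dbs])


def expressed_mirnas(expr: pd.DataFrame, cpm_threshold: float = 100.0,
                     min_lines: int = 4, direction: str = "ge") -> set:
    """miRNAs passing the CPM threshold in at least ``min_lines`` cell lines.

    ``direction='ge'`` keeps lines with mean CPM >= threshold (the default
    reading), ``'lt'`` the literal below-threshold variant.
    """
    mean_cpm = expr.groupby(["mirna_id", "cell_line"])["cpm"].mean()
    if direction == "ge":
        passing = mean_cpm >= cpm_threshold
    elif direction == "lt":
        passing = mean_cpm < cpm_threshold
    else:
        raise ValueError("direction must be 'ge' or 'lt'")
    n_lines = passing.groupby("mirna_id").sum()
    return set(n_lines.index[n_lines >= min_lines])


def targeting_counts(pairs: set, genes: set, mirnas: set,
                     family_map: dict | None = None
                     ) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Counts over the consensus pairs restricted to ``genes`` x ``mirnas``.

    Returns (gene -> number of distinct targeting miRNAs,
    miRNA -> number of target genes, family -> number of target genes);
    a gene targeted by several members of one family counts once for that
    family. Genes and miRNAs without interactions appear with count 0.
    """
    kept = [(m, g) for m, g in pairs if g in genes and m in mirnas]
    df = pd.DataFrame(kept, columns=["mirna_id", "gene_id"])
    per_gene = (df.groupby("gene_id")["mirna_id"].nunique()
                .reindex(sorted(genes), fill_value=0))
    per_mirna = (df.groupby("mirna_id")["gene_id"].nunique()
                 .reindex(sorted(mirnas), fill_value=0))
    if family_map:
        df["family"] = df["mirna_id"].map(lambda m: family_map.get(m, m))
        per_family = df.drop_duplicates(["family", "gene_id"]).groupby("family").size()
    else:
        per_family = pd.Series(dtype=int)
    return per_gene, per_mirna, per_family
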