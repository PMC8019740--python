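"""CLIP peak significance filtering, peak-gene intersection, and the
binding-based partition into DPP_CLIP / NDP_noCLIP / UNP_CLIP sets.

Peaks are kept when at least eight-fold enriched over input with an
enrichment p-value strictly below 1e-5. Intersection is strand-agnostic
over 0-based half-open intervals: a peak is assigned to every gene whose
genomic span (union of transcript spans, introns included) it overlaps by
at least one nucleotide.
"""

from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModels

logger = logging.getLogger(__name__)


def filter_peaks(peaks: pd.DataFrame, min_fold: float = 8.0,
                 max_p: float = 1e-5) -> pd.DataFrame:
    """Retain peaks with fold_enrichment >= min_fold and p_value < max_p."""
    bad = peaks[(peaks["fold_enrichment"] < 0) | (peaks["p_value"] <= 0) |
                (peaks["p_value"] > 1)]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"malformed peak {r['chrom']}:{r['start']}-{r['end']} "
            f"(fold={r['fold_enrichment']}, p={r['p_value']})")
    keep = (peaks["fold_enrichment"] >= min_fold) & (peaks["p_value"] < max_p)
    return peaks.loc[keep].copy()


def overlap_genes(peaks: pd.DataFrame, genes: GeneModels,
                  exonic_only: bool = False) -> pd.DataFrame:
    """Per-gene binding summary: total peak count and distinct samples.

    With ``exonic_only`` the peak must overlap an exon of some transcript
    rather than merely the intron-inclusive gene span. Every gene in the
    annotation gets a row (zero counts when unbound).
    """
    trees: dict[str, IntervalTree] = {}
    for gid in genes.gene_ids:
        chrom, s, e = genes.gene_span(gid)
        tree = trees.setdefault(chrom, IntervalTree())
        if exonic_only:
            for t in genes.by_gene[gid]:
                for es, ee in t.exons:
                    tree.addi(es, ee, gid)
        else:
            tree.addi(s, e, gid)
    hits: dict[str, list] = {g: [] for g in genes.gene_ids}
    n_unknown = 0
    for row in peaks.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            n_unknown += 1
            continue
        for iv in tree.overlap(row.start, row.end):
            hits[iv.data].append((row.Index, row.sample_id))
    if n_unknown:
        logger.info("overlap_genes: skipped %d peak(s) on unknown chrom", n_unknown)
    return pd.DataFrame({
        "gene_id": genes.gene_ids,
        "n_samples_with_peak": [len({s for _, s in hits[g]}) for g in genes.gene_ids],
        "n_peaks_total": [len({i for i, _ in hits[g]}) for g in genes.gene_ids],
    })


def partition_by_binding(labels: pd.DataFrame, summaries: pd.DataFrame
                         ) -> tuple[set, set, set]:
    """(DPP_CLIP, NDP_noCLIP, UNP_CLIP) from class labels + binding summaries.

    ``summaries`` must come from significance-filtered peaks only.
    """
    bound = set(summaries.loc[summaries["n_samples_with_peak"] >= 1, "gene_id"])
    lab = labels.set_index("gene_id")["label"]
    dpp = set(lab.index[lab == "DPP"])
    ndp = set(lab.index[lab == "NDP"])
    unp = set(lab.index[lab == "UNP"])
    return dpp & bound, ndp - bound, unp & bound
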