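"""End-to-end orchestration: DE tables -> consistency calls -> pan-cancer
correlation labels -> CLIP partition -> length-matched control set ->
per-gene feature annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import clip, consistency, correlation, features, matching
from .models import GeneModels
from .synthetic import SimulationBundle


@dataclass
class PipelineResult:
    calls: pd.DataFrame  # per-gene consistency status (protein-coding)
    lincrna_calls: pd.DataFrame  # lincRNA genes, reported separately
    tallies: pd.DataFrame
    labels: pd.DataFrame  # UNP/DPP/NDP/unlabeled
    binding: pd.DataFrame  # per-gene CLIP summary (filtered peaks)
    dpp: set = field(default_factory=set)
    unp: set = field(default_factory=set)
    ndp: set = field(default_factory=set)
    dpp_clip: set = field(default_factory=set)
    ndp_noclip: set = field(default_factory=set)
    unp_clip: set = field(default_factory=set)
    ndp_noclip_lm: set = field(default_factory=set)
    match: matching.MatchResult | None = None
    feature_tables: dict = field(default_factory=dict)


def run(bundle: SimulationBundle, fdr_sig: float = 0.05,
        fdr_stable: float = 0.95, min_cohorts: int = 20,
        min_fold: float = 8.0, max_p: float = 1e-5,
        match_seed: int = 0) -> PipelineResult:
    """Run the full target-calling pipeline on one input bundle."""
    cfg = bundle.cfg
    pc_tables = [consistency.filter_biotype(t, {"protein_coding"})
                 for t in bundle.deg_tables]
    calls = consistency.classify_consistency(pc_tables, fdr_sig, fdr_stable)
    linc_tables = [consistency.filter_biotype(t, {"lincRNA"})
                   for t in bundle.deg_tables]
    if all(len(t) for t in linc_tables):
        linc_calls = consistency.classify_consistency(linc_tables, fdr_sig, fdr_stable)
    else:
        linc_calls = pd.DataFrame(columns=["gene_id", "status",
                                           "n_experiments_significant"])

    dereg = sorted(consistency.status_genes(calls, "cons_down") |
                   consistency.status_genes(calls, "cons_up"))
    tallies = correlation.tally_signs(cfg.driver_gene, dereg, bundle.cohorts)
    labels = correlation.assign_labels(calls, tallies, min_cohorts=min_cohorts)

    sig_peaks = clip.filter_peaks(bundle.peaks, min_fold=min_fold, max_p=max_p)
    binding = clip.overlap_genes(sig_peaks, bundle.models)
    dpp_clip, ndp_noclip, unp_clip = clip.partition_by_binding(labels, binding)

    lengths = dict(bundle.models.max_utr3_table())
    result = PipelineResult(
        calls=calls, lincrna_calls=linc_calls, tallies=tallies, labels=labels,
        binding=binding,
        dpp=correlation.label_genes(labels, "DPP"),
        unp=correlation.label_genes(labels, "UNP"),
        ndp=correlation.label_genes(labels, "NDP"),
        dpp_clip=dpp_clip, ndp_noclip=ndp_noclip, unp_clip=unp_clip)
    if dpp_clip and len(ndp_noclip) >= len(dpp_clip):
        result.match = matching.match_by_length(dpp_clip, ndp_noclip, lengths,
                                                seed=match_seed)
        result.ndp_noclip_lm = result.match.matched_ids

    for name, gene_set in (("DPP_CLIP", dpp_clip), ("NDP_noCLIP", ndp_noclip),
                           ("NDP_noCLIP_LM", result.ndp_noclip_lm)):
        if gene_set:
            result.feature_tables[name] = features.feature_table(
                sorted(gene_set), bundle.models, bundle.m6a,
                bundle.utr3_seqs, list(cfg.motifs))
    return result
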