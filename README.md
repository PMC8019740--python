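# rbptargets

Calling conserved RNA-binding-protein-stabilized candidate target mRNAs by
integrating multi-cell-line knockdown differential expression, pan-cancer
expression correlation, CLIP binding, and 3'UTR regulatory-feature
annotation — with a fully seeded synthetic-data generator that plants
ground truth so every stage of the pipeline is verifiable at desk scale.

## The problem

Oncofetal RBPs such as IGF2BP1 stabilize mRNAs encoding pro-oncogenic
factors, but CLIP binding alone nominates thousands of transcripts. The
strategy implemented here narrows them down by requiring *conserved
regulation*: a candidate must (i) drop significantly (FDR < 0.05,
log2FC < 0) in **every** knockdown experiment across cell lines, (ii)
correlate positively (Spearman ρ > 0) with the driver gene's expression in
at least 20 of 31 tumor cohorts (a **DPP**: downregulated,
positively-correlated protein-coding gene), and (iii) carry at least one
significant CLIP peak (≥ 8-fold enriched over input, enrichment p < 1e-5)
in any binding sample (**DPP_CLIP**). Controls come from genes unchanged in
every experiment (FDR ≥ 0.95; **NDP**) without any significant peak
(**NDP_noCLIP**), plus a 3'UTR-length-matched subset (**NDP_noCLIP_LM**)
that separates length-driven feature differences from binding-driven ones.
Downstream modules quantify 3'UTR length, m6A load, AU-rich elements,
miRNA consensus targeting (≥ 2 of 8 prediction databases), stop-codon
meta-gene profiles (30 bins per region), median-split log-rank hazard
ratios (HR = (O/E)high / (O/E)low), unweighted preranked GSEA, and
hypergeometric ORA with a subsampling null for TF-family enrichment.

See `docs/methods.md` for the full model, parameter meanings and
limitations.

## Worked example

```python
from rbptargets import pipeline
from rbptargets.synthetic import SimulationConfig, simulate

bundle = simulate(SimulationConfig(seed=1))   # 1,000 genes, 6 experiments,
res = pipeline.run(bundle, match_seed=1)      # 31 cohorts, planted truth
planted = bundle.truth_genes("target_down")
print(len(res.dpp), len(res.dpp & planted) / len(res.dpp))
print(len(res.dpp_clip), res.match.target_median_len,
      res.match.matched_median_len)
```

prints

```
60 1.0
39 2212.0 2267.0
```

— all 60 planted conserved-down genes are recovered as DPPs with precision
1.0; the 39 CLIP-bound ones form DPP_CLIP, whose median maximum 3'UTR
length (2,212 nt) is reproduced by the length-matched control set
(2,267 nt) drawn from the short-3'UTR null pool. The `examples/` scripts
walk through each capability (target calling, peak filtering and meta-gene
profiles, survival hazards, enrichment and the subsampling null, miRNA
consensus and 3'UTR features) and print the numbers they compute.

A thin CLI mirrors the two entry points:

```sh
rbptargets simulate --outdir sim/ --seed 1   # write all inputs + truth
rbptargets run --seed 1                      # simulate + call targets
```

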