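"""miRNA consensus targeting and 3'UTR regulatory features by gene set.

Builds >=2-of-8-database consensus pairs restricted to expressed miRNAs,
then compares bound targets against unbound stable controls for distinct
targeting miRNAs, 3'UTR length, m6A load and ARE content.
"""

from rbptargets import features, pipeline
from rbptargets.mirna import consensus_pairs, expressed_mirnas, targeting_counts
from rbptargets.synthetic import SimulationConfig, simulate

bundle = simulate(SimulationConfig(seed=1))
res = pipeline.run(bundle, match_seed=1)

mirnas = expressed_mirnas(bundle.mirna_expr, cpm_threshold=100, min_lines=4)
pairs = consensus_pairs(bundle.mirna_preds,
                        sorted(set(bundle.mirna_preds["db_name"])))
per_gene, per_mirna, per_family = targeting_counts(
    pairs, res.dpp_clip | res.ndp_noclip, mirnas,
    family_map=dict(zip(bundle.mirna_families["mirna_id"],
                        bundle.mirna_families["family"])))
print(f"expressed miRNAs (>=100 CPM in >=4 lines): {len(mirnas)}")
print(f"median distinct miRNAs per gene — DPP_CLIP: "
      f"{per_gene[sorted(res.dpp_clip)].median():.0f}, "
      f"NDP_noCLIP: {per_gene[sorted(res.ndp_noclip)].median():.0f}")

for name in ("DPP_CLIP", "NDP_noCLIP", "NDP_noCLIP_LM"):
    ft = res.feature_tables[name]
    print(f"{name}: median 3'UTR {ft['max_utr3_len'].median():.0f} nt, "
          f"median m6A sites {ft['m6a_sites'].median():.0f}, "
          f"ARE fraction {ft['has_are'].mean():.2f}")

_, p = features.compare_groups(res.feature_tables["DPP_CLIP"]["m6a_sites"],
                               res.feature_tables["NDP_noCLIP"]["m6a_sites"],
                               alternative="greater")
print(f"m6A DPP_CLIP > NDP_noCLIP: Mann-Whitney p = {p:.2e}")
# Bound targets carry more miRNA sites, longer 3'UTRs and higher m6A load;
# the length-matched control row shows which differences survive matching.
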