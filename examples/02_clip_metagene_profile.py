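"""Filter CLIP peaks to significance and profile them along transcripts.

The meta-gene profile pools peak midpoints over 30 bins each of 5'UTR,
CDS and 3'UTR of the bound genes' longest-3'UTR transcripts; bins 59/60
straddle the stop codon.
"""

from rbptargets import clip, metagene, pipeline
from rbptargets.synthetic import SimulationConfig, simulate

bundle = simulate(SimulationConfig(seed=1))
res = pipeline.run(bundle, match_seed=1)

sig = clip.filter_peaks(bundle.peaks, min_fold=8.0, max_p=1e-5)
print(f"peaks passing the >=8-fold, p<1e-5 filter: "
      f"{len(sig)} of {len(bundle.peaks)}")

prof = metagene.aggregate_profile(sig, bundle.models,
                                  gene_ids=sorted(res.dpp_clip))
print(f"profile mass sums to {prof.bins.sum():.6f} over {prof.n_sites} sites")
print(f"modal bin: {prof.mode_bin} (stop codon boundary is bin 59/60)")
top = prof.to_frame().nlargest(3, "frequency")
print(top.to_string(index=False))
# A mode at bin 59-60 reproduces the stop-codon-proximal binding signature.
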