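# Methods

`rbptargets` re-implements, as a tested library, an integrative strategy for
nominating mRNAs that an oncogenic RNA-binding protein (RBP) stabilizes in a
conserved fashion across cancer models. The driver gene plays the role of
IGF2BP1-like regulators: knocking it down lowers the abundance of its
stabilized targets in every cell line, its expression correlates positively
with those targets across tumor cohorts, and its binding leaves CLIP peaks
near their stop codons. No external accessions are required: a seeded
generator produces all inputs with planted ground truth so every stage can
be verified end to end.

## The calling procedure

1. **Cross-experiment consistency.** Each knockdown experiment contributes a
   per-gene table of log2 fold change and FDR. After restricting to
   protein-coding genes (lincRNAs are classified separately and not passed
   downstream), a gene is *consistently down* when FDR < 0.05 (strict) with
   log2FC < 0 in **every** experiment; *consistently up* symmetrically;
   *consistently unchanged* when FDR ≥ 0.95 everywhere. Genes missing from
   any table, with a sign conflict, or with log2FC = 0 are *inconsistent* —
   the signed sets require evidence in all experiments.
2. **Pan-cancer correlation.** Spearman's ρ (mid-rank Pearson; ties get
   average ranks) is computed per cohort between each consistently
   deregulated gene and the driver. ρ is undefined when either rank vector
   is constant; such cohorts count to neither sign, and ρ = 0 counts to
   neither tally. A down gene positively correlated in ≥ 20 of 31 cohorts is
   a **DPP**; an up gene negatively correlated in ≥ 20 a **UNP**; every
   consistently unchanged gene is an **NDP** regardless of its correlations.
   The 20-of-31 threshold is not rescaled when a gene is missing from some
   cohorts.
3. **CLIP partition.** Peaks are significant when ≥ 8-fold enriched over
   input with enrichment p < 1e-5 (both boundaries follow the removal rule:
   "less than eight-fold" and "p ≥ 1e-5" are discarded, so fold = 8 is kept
   and p = 1e-5 is not). Intersection with intron-inclusive gene spans is
   strand-agnostic over 0-based half-open intervals, ≥ 1 nt overlap
   (an `exonic_only` switch restricts to exons). DPPs with ≥ 1 significant
   peak in any sample form **DPP_CLIP**; NDPs with none form **NDP_noCLIP**.
4. **Length-matched control.** For each DPP_CLIP gene, the unused NDP_noCLIP
   gene nearest in log10(max-3'UTR-length + 1) is selected greedily, in
   seeded random order, without replacement (**NDP_noCLIP_LM**). The log
   scale reflects the heavy upper tail of 3'UTR lengths. Matching reports
   both medians rather than enforcing a gap: with an adversarial pool the
   size invariant still holds and the (poor) gap is visible in the output.
5. **Feature comparison.** Per gene: the maximum 3'UTR length over isoforms
   (the longest-3'UTR transcript is "designated" for all per-transcript
   analyses); the per-gene maximum of exonic m6A site counts over
   transcripts (intronic sites never count); an ARE flag; overlapping IUPAC
   4-mer motif densities normalized to |seq| − 3. Group differences use the
   Mann-Whitney test (exact by enumeration when the pooled n ≤ 12 and
   tie-free, otherwise the tie-corrected normal approximation with
   continuity correction).

## Supporting statistics

- **GSEA (unweighted, preranked).** Running sum +1/N_hit at members,
  −1/N_miss elsewhere; the ES is the signed value of maximal absolute
  deviation. The sum is computed in integers (steps scaled by
  N_hit·N_miss), so exact magnitude ties resolve deterministically to the
  first position. Significance comes from random equal-size gene sets drawn
  from the ranked universe — a deliberate divergence from fgsea's adaptive
  multilevel algorithm, so p-values are permutation-grade:
  p = (1 + #{|ES₀| ≥ |ES|, same sign}) / (1 + #same-sign permutations),
  NES = ES / mean(|ES₀| same sign). Score ties in rankings break by gene id.
- **ORA.** Right-sided hypergeometric tail P(X ≥ overlap) with
  Benjamini-Hochberg correction across terms.
- **TF subsampling null.** Draw query-sized gene sets from the NDP pool
  without replacement, run per-TF ORA against the pool as universe, BH
  within each draw, and count significantly enriched family TFs. This
  replaces a motif-AUC ranking tool with a transparent overlap test; only
  the subsampling construction itself is asserted.
- **Survival.** Samples split at the gene's median expression; ties at the
  median go to "low" (configurable) so "high" means strictly above. The
  log-rank statistic is the O/E risk-table walk, χ² = Σ_g (O_g − E_g)²/E_g
  on 1 df, with HR = (O_high/E_high)/(O_low/E_low) — the classical
  textbook description, not a Cox fit and not lifelines' variance-based
  statistic. Censored samples at an event time remain at risk at that time.
  HR is flagged undefined (NaN) when a group has zero observed or expected
  events, and such cohorts drop out of pan-cohort medians.
- **Meta-gene profiles.** 30 bins per region (5'UTR, CDS, 3'UTR) on the
  designated transcript; peak intervals contribute their midpoints
  (interval smearing available behind a flag); pooled counts are normalized
  once, so transcripts lacking a region simply contribute nothing there.
  Position r ∈ [0,1) within a region maps to ⌊30·r⌋, clamped so the last
  base lands in the region's final bin.
- **ARE scanner.** The database lookup the original analysis used is not
  reproducible offline; the scanner is a documented surrogate: a 3'UTR has
  an ARE when at least one AUUUA pentamer sits in a 13-nt window (4-nt
  flanks, truncated at ends) that is ≥ 10/13 A/U. T and U are equivalent on
  input. A precomputed ARE column can bypass the scanner.
- **miRNA consensus.** A miRNA-gene pair is retained when ≥ 2 of the 8
  configured databases report it (duplicates within one database count
  once). The expressed-miRNA filter averages CPM per cell line across
  replicates and keeps miRNAs passing in ≥ 4 lines. The printed source
  description of this filter ("average expression <100 CPM") contradicts
  its purpose of selecting expressed miRNAs; the default is ≥ 100 CPM with
  `direction="lt"` available, and neither reading is asserted as intent.

## The synthetic generator

Defaults emulate the study conditions: 6 experiments, 31 cohorts of 200
samples, 1,000 genes with 60/12/300 planted down/up/stable genes, 65% of
down targets CLIP-bound, |log2FC| = 2 (σ = 0.3), correlation coupling
ρ = 0.9, planted log2 HR = 1.0, 6 CLIP samples, 150 miRNAs over 6 cell
lines and 8 databases (sensitivity 0.7, false-positive rate 0.02 each,
modeled as independent noisy views of one true interaction matrix).

- DE tables are drawn directly on the (FDR, log2FC) scale — count-level
  simulation plus model fitting is out of scope. Planted classes satisfy
  their defining rule in every experiment; background genes are significant
  in at most n−1 experiments with random signs, so no background gene can
  pass either all-experiment rule. This makes the default run "noise-free"
  at the decision boundaries: recovery failures would indicate
  implementation defects, not sampling noise.
- Annotation: one contig per 50 genes, 1 kb spacing, 0-based half-open
  coordinates; 1-3 transcripts per gene sharing 5'UTR/CDS and differing in
  3'UTR length; 1-3 exons with 80-800 nt introns. Maximum 3'UTR lengths are
  lognormal — targets (μ = ln 2300, σ = 0.6), others (μ = ln 420, σ = 1.2).
  Medians mirror the ~2,300 vs ~420 nt contrast; the wider null tail makes
  the two distributions overlap as real 3'UTR lengths do, which is what
  gives the length-matching step a workable pool.
- Sequences are A/U-poor random RNA (P(A)=P(U)=0.2) so chance AREs stay
  rare; ARE cassettes are planted with probability 1 − exp(−len/4000),
  i.e. ARE content is driven by 3'UTR length for every class (~44% at
  2,300 nt vs ~10% at 420 nt), and configured 4-mer motifs are inserted at
  an elevated rate on targets.
- Cohort expression is exp(latent Gaussian); coupling acts on the latent
  scale and Spearman only sees ranks. Survival is exponential with
  administrative censoring at a horizon chosen for ~30% censoring; the
  hazard doubles (2^log2HR) above the prognostic gene's median expression.
  One gene is designated prognostic so its marginal HR is exactly the
  planted value.
- Significant CLIP peaks are 40-nt intervals centered N(0, 25) nt around
  the stop codon in mature coordinates on bound genes; unbound genes
  receive only sub-threshold decoys (failing fold or p). m6A counts are
  Poisson(25) on targets; elsewhere presence and count grow with 3'UTR
  length, so the length-matched control set lands near the ~3-site median
  that long unbound transcripts show.
- Setting `rho_strength=0` (or `hazard_log2hr=0`) removes the coupling
  *and* the planted correlation signs, giving exact null conditions for
  calibration tests.

What the generator does **not** emulate: realistic sequence composition
beyond planted motifs, read-level noise, inter-gene expression correlation
structure, batch effects, cohort-size heterogeneity, or biotype-specific
biology. Passing tests therefore demonstrate correctness of the decision
rules and statistics under the stated model, not robustness to the messier
failure modes of real data.

## Verification set-up and problem sizes

The test suite checks each operation against independent oracles
(brute-force interval intersection at 1,000 × 1,000; exact-fraction GSEA
running sums over all subsets of 8-gene lists; full rank-assignment
enumeration for small Mann-Whitney; a 1e5-draw urn simulation for ORA;
hand-walked log-rank risk tables) and calibrates null behaviour on runs
with ≥ 500 uncoupled genes across 31 cohorts. `scripts/acceptance.py`
re-runs the default study (1,000 genes) from scratch and reports recovery,
calibration and figure-level statistics; these sizes keep a full run in a
few seconds on one CPU while leaving the binomial/KS calibration bands
narrow enough to be informative.

## Known limitations

- GSEA p-values and the BH-over-permutation FDR approximate, but are not,
  fgsea's multilevel estimates; outputs are labeled accordingly.
- The O/E hazard-ratio estimator is slightly biased away from 1 for strong
  effects relative to a Cox estimate; the parameter-recovery test bounds
  this at the study scale (±0.3 on log2 HR).
- Greedy nearest-neighbour matching is not optimal transport; with sparse
  pools individual matches can be poor even when the medians agree.
- The consistency rules are all-or-nothing across experiments; a single
  missing measurement removes a gene from every conserved set.
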