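"""Synthetic multi-omics inputs with planted ground truth.

Emulates the study design the pipeline consumes: six knockdown
differential-expression experiments, 31 tumor-like cohorts with
expression/survival coupling to a driver gene, CLIP peak files from several
samples with stop-codon-proximal binding on planted targets, m6A site
tables, an eight-database miRNA target-prediction compendium with a
cell-line CPM table, and a TF->gene motif annotation in which one TF family
preferentially covers the planted down-regulated targets.

Every gene carries exactly one truth label (``target_down``, ``target_up``,
``stable_null`` or ``background``); the truth table is emitted alongside the
data so each downstream stage can be scored against it. Generation is fully
driven by a single :class:`numpy.random.Generator` seeded from the config,
so identical configs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import CohortData
from .io import write_fasta, write_gtf, write_peaks_bed, write_tsv
from .models import GeneModels, TranscriptModel

LABELS = ("target_down", "target_up", "stable_null", "background")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 0
    n_genes: int = 1000
    n_experiments: int = 6
    n_cohorts: int = 31
    n_planted_down: int = 60
    n_planted_up: int = 12
    n_planted_null: int = 300
    frac_clip_on_targets: float = 0.65
    effect_log2fc: float = 2.0
    lfc_sigma: float = 0.3
    rho_strength: float = 0.9
    hazard_log2hr: float = 1.0
    n_samples_per_cohort: int = 200
    # (mu, sigma) of log 3'UTR length per class; medians ~2300 nt vs ~420 nt.
    # The null class is wider so its upper tail overlaps the target range,
    # as real 3'UTR length distributions do — length matching needs that.
    utr3_lognormal_params: dict = field(default_factory=lambda: {
        "target": (math.log(2300.0), 0.6),
        "null": (math.log(420.0), 1.2),
    })
    n_clip_samples: int = 6
    n_mirnas: int = 150
    n_cell_lines: int = 6
    n_databases: int = 8
    db_sensitivity: float = 0.7
    db_fpr: float = 0.02
    base_hazard: float = 1.0
    censor_horizon: float = 0.85  # administrative censoring, ~30% censored
    genes_per_contig: int = 50
    intergenic_gap: int = 1000
    are_length_scale: float = 4000.0  # ARE planting prob = 1 - exp(-len/scale)
    motifs: tuple = ("CAUH", "GGAC")
    driver_gene: str = "DRIVER"

    def __post_init__(self) -> None:
        if self.n_planted_down + self.n_planted_up + self.n_planted_null > self.n_genes:
            raise ValueError("planted classes exceed n_genes")
        for name in ("n_genes", "n_experiments", "n_cohorts", "n_planted_down",
                     "n_planted_up", "n_planted_null", "n_samples_per_cohort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_clip_on_targets <= 1.0:
            raise ValueError("frac_clip_on_targets must be in [0,1]")


@dataclass
class SimulationBundle:
    """Everything one seeded run produced, in memory."""

    cfg: SimulationConfig
    truth: pd.DataFrame  # gene_id, label, corr_sign, clip_bound, prognostic
    models: GeneModels
    utr3_seqs: dict  # transcript_id -> RNA string
    deg_tables: list  # one DataFrame per experiment
    cohorts: list  # CohortData per cohort
    peaks: pd.DataFrame  # all CLIP samples pooled, canonical peak frame
    m6a: pd.DataFrame  # chrom, pos, strand
    mirna_expr: pd.DataFrame  # mirna_id, cell_line, cpm
    mirna_preds: pd.DataFrame  # mirna_id, gene_id, db_name
    mirna_families: pd.DataFrame  # mirna_id, family
    tf_annotation: pd.DataFrame  # tf_id, gene_id
    peak_positions: dict  # gene_id -> list of planted significant peak centers

    def truth_genes(self, label: str) -> set:
        return set(self.truth.loc[self.truth["label"] == label, "gene_id"])

    @property
    def clip_bound_genes(self) -> set:
        return set(self.truth.loc[self.truth["clip_bound"], "gene_id"])


def _gene_ids(n: int) -> list:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _plant_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = _gene_ids(cfg.n_genes)
    labels = np.array(["background"] * cfg.n_genes, dtype=object)
    perm = rng.permutation(cfg.n_genes)
    n_d, n_u, n_n = cfg.n_planted_down, cfg.n_planted_up, cfg.n_planted_null
    labels[perm[:n_d]] = "target_down"
    labels[perm[n_d:n_d + n_u]] = "target_up"
    labels[perm[n_d + n_u:n_d + n_u + n_n]] = "stable_null"
    corr_sign = np.where(labels == "target_down", 1,
                         np.where(labels == "target_up", -1, 0))
    if cfg.rho_strength == 0.0:
        corr_sign = np.zeros(cfg.n_genes, dtype=int)
    down_idx = np.flatnonzero(labels == "target_down")
    n_bound = int(round(cfg.frac_clip_on_targets * len(down_idx)))
    bound = np.zeros(cfg.n_genes, dtype=bool)
    bound[rng.choice(down_idx, size=n_bound, replace=False)] = True
    # a minority of the up-regulated targets is CLIP-bound as well
    up_idx = np.flatnonzero(labels == "target_up")
    if len(up_idx) > 0:
        n_up_bound = int(round(0.4 * len(up_idx)))
        bound[rng.choice(up_idx, size=n_up_bound, replace=False)] = True
    prognostic = np.zeros(cfg.n_genes, dtype=bool)
    if cfg.hazard_log2hr != 0.0 and len(down_idx) > 0:
        prognostic[down_idx[0]] = True
    return pd.DataFrame({
        "gene_id": genes, "label": labels, "corr_sign": corr_sign,
        "clip_bound": bound, "prognostic": prognostic,
    })


# ------------------------------------------------------------------ annotation

_NT = np.array(list("ACGU"))
_NT_P = np.array([0.2, 0.3, 0.3, 0.2])  # AU-poor background to keep chance AREs rare
_IUPAC_CHOICES = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
                  "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU",
                  "M": "AC", "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
                  "N": "ACGU"}

_ARE_CASSETTE = "UAUUUAUUUAUUU"  # two overlapping AUUUA pentamers, AU-rich


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NT, size=n, p=_NT_P))


def _plant(seq: str, insert: str, rng: np.random.Generator) -> str:
    if len(insert) >= len(seq):
        return insert[: len(seq)]
    pos = int(rng.integers(0, len(seq) - len(insert) + 1))
    return seq[:pos] + insert + seq[pos + len(insert):]


def _concrete_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_IUPAC_CHOICES[c])) for c in motif.upper())


def _build_transcript(tid: str, gene_id: str, chrom: str, strand: str,
                      gene_start: int, u5: int, cds: int, u3: int,
                      rng: np.random.Generator) -> TranscriptModel:
    mature = u5 + cds + u3
    n_exons = int(rng.integers(1, 4))
    if n_exons > 1:
        bps = np.sort(rng.choice(np.arange(1, mature), size=n_exons - 1, replace=False))
    else:
        bps = np.array([], dtype=int)
    seg_lens = np.diff(np.concatenate([[0], bps, [mature]]))
    exons, cursor = [], gene_start
    for i, L in enumerate(seg_lens):
        exons.append((cursor, cursor + int(L)))
        cursor += int(L)
        if i < len(seg_lens) - 1:
            cursor += int(rng.integers(80, 801))
    cum = np.concatenate([[0], np.cumsum(seg_lens)])

    def plus_to_genomic(p: int) -> int:
        i = int(np.searchsorted(cum, p, side="right")) - 1
        return exons[i][0] + (p - int(cum[i]))

    # mature CDS interval is [u5, u5+cds); on '-' the plus-layout runs 3'->5'
    mf, ml = u5, u5 + cds - 1
    if strand == "-":
        mf, ml = mature - 1 - mf, mature - 1 - ml
    g1, g2 = plus_to_genomic(mf), plus_to_genomic(ml)
    return TranscriptModel(
        transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(exons), cds_start=min(g1, g2), cds_end=max(g1, g2) + 1)


def generate_annotation(cfg: SimulationConfig, truth: pd.DataFrame,
                        rng: np.random.Generator) -> tuple[GeneModels, dict]:
    """Gene models (1-3 transcripts each) plus per-transcript 3'UTR sequences.

    Target-class genes draw their maximum 3'UTR length from the long-tailed
    distribution, all other genes from the short one; ARE cassettes are
    planted with a probability that grows with 3'UTR length, and the
    configured 4-mer motifs are inserted at an elevated rate on targets.
    """
    mu_t, sd_t = cfg.utr3_lognormal_params["target"]
    mu_n, sd_n = cfg.utr3_lognormal_params["null"]
    transcripts, seqs = [], {}
    cursor, contig_idx = 0, 0
    for i, row in enumerate(truth.itertuples()):
        if i % cfg.genes_per_contig == 0:
            contig_idx += 1
            cursor = 0
        chrom = f"ctg{contig_idx:03d}"
        is_target = row.label in ("target_down", "target_up")
        mu, sd = (mu_t, sd_t) if is_target else (mu_n, sd_n)
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = max(20, int(rng.lognormal(math.log(150.0), 0.4)))
        cds = 3 * max(40, int(rng.lognormal(math.log(140.0), 0.4)))
        u3_max = max(30, int(rng.lognormal(mu, sd)))
        n_tx = int(rng.integers(1, 4))
        u3s = [u3_max] + [max(20, int(u3_max * rng.uniform(0.2, 0.8)))
                          for _ in range(n_tx - 1)]
        gene_end = cursor
        for k, u3 in enumerate(u3s, start=1):
            tid = f"{row.gene_id}.t{k}"
            t = _build_transcript(tid, row.gene_id, chrom, strand, cursor,
                                  u5, cds, u3, rng)
            transcripts.append(t)
            gene_end = max(gene_end, t.span[1])
            seq = _random_seq(rng, u3)
            if rng.random() < 1.0 - math.exp(-u3 / cfg.are_length_scale):
                seq = _plant(seq, _ARE_CASSETTE, rng)
            motif_rate = 1.0 / 300.0 if is_target else 1.0 / 2000.0
            for motif in cfg.motifs:
                for _ in range(rng.poisson(motif_rate * u3)):
                    seq = _plant(seq, _concrete_motif(motif, rng), rng)
            seqs[tid] = seq
        cursor = gene_end + cfg.intergenic_gap
    return GeneModels.from_transcripts(transcripts), seqs


# ------------------------------------------------------------------ DE tables

def generate_de_tables(cfg: SimulationConfig, truth: pd.DataFrame,
                       rng: np.random.Generator) -> list:
    """One differential-expression table per knockdown experiment.

    Planted down/up targets are significant with the configured effect in
    every experiment; stable nulls sit above the high-confidence FDR floor
    everywhere; background genes receive mixed signals (significant in at
    most ``n_experiments - 1`` experiments, with random signs) so that no
    background gene can satisfy either all-experiment rule.
    """
    n = cfg.n_genes
    labels = truth["label"].to_numpy()
    biotype = np.where(labels != "background", "protein_coding",
                       rng.choice(["protein_coding", "lincRNA", "other"],
                                  size=n, p=[0.8, 0.1, 0.1]))
    n_sig = rng.integers(0, cfg.n_experiments, size=n)  # background only
    sig_exp = [set(rng.choice(cfg.n_experiments, size=k, replace=False))
               for k in n_sig]
    tables = []
    for e in range(cfg.n_experiments):
        fdr = rng.uniform(0.05, 0.95, size=n)
        lfc = rng.normal(0.0, cfg.lfc_sigma, size=n)
        down, up = labels == "target_down", labels == "target_up"
        fdr[down | up] = rng.uniform(0.0, 0.05, size=int((down | up).sum()))
        lfc[down] = rng.normal(-cfg.effect_log2fc, cfg.lfc_sigma, size=int(down.sum()))
        lfc[down] = np.minimum(lfc[down], -0.1)
        lfc[up] = rng.normal(cfg.effect_log2fc, cfg.lfc_sigma, size=int(up.sum()))
        lfc[up] = np.maximum(lfc[up], 0.1)
        stable = labels == "stable_null"
        fdr[stable] = rng.uniform(0.95, 1.0, size=int(stable.sum()))
        bg = labels == "background"
        bg_sig = bg & np.array([e in s for s in sig_exp])
        fdr[bg_sig] = rng.uniform(0.0, 0.05, size=int(bg_sig.sum()))
        lfc[bg_sig] = rng.choice([-1.0, 1.0], size=int(bg_sig.sum())) * \
            np.abs(rng.normal(cfg.effect_log2fc / 2, cfg.lfc_sigma, size=int(bg_sig.sum())))
        tables.append(pd.DataFrame({
            "gene_id": truth["gene_id"], "biotype": biotype,
            "log2fc": lfc, "fdr": fdr,
        }))
    return tables


# ------------------------------------------------------------------ cohorts

def generate_cohorts(cfg: SimulationConfig, truth: pd.DataFrame,
                     rng: np.random.Generator) -> list:
    """Expression matrices coupled to the driver gene, plus survival.

    Driver expression is latent standard normal per sample; target_down
    genes receive ``rho*z + sqrt(1-rho^2)*noise`` (positive association),
    target_up the negated coupling. Matrices are exponentiated to an
    FPKM-like non-negative scale (rank structure, hence Spearman, is
    unchanged). Survival is exponential with the hazard multiplied by
    ``2**hazard_log2hr`` for samples above the prognostic gene's median
    expression, censored administratively at the configured horizon.
    """
    n, m = cfg.n_genes, cfg.n_samples_per_cohort
    signs = truth["corr_sign"].to_numpy()[:, None]
    rho = cfg.rho_strength
    prog_idx = np.flatnonzero(truth["prognostic"].to_numpy())
    cohorts = []
    for c in range(cfg.n_cohorts):
        z = rng.normal(size=m)
        eps = rng.normal(size=(n, m))
        zg = np.where(signs != 0, signs * rho * z[None, :] +
                      math.sqrt(max(0.0, 1 - rho * rho)) * eps, eps)
        expr = pd.DataFrame(np.exp(np.vstack([z, zg])),
                            index=[cfg.driver_gene] + list(truth["gene_id"]),
                            columns=[f"S{c:02d}_{j:03d}" for j in range(m)])
        rate = np.full(m, cfg.base_hazard)
        if len(prog_idx) > 0:
            pe = zg[prog_idx[0]]
            rate = rate * np.power(2.0, cfg.hazard_log2hr * (pe > np.median(pe)))
        t_event = rng.exponential(1.0 / rate)
        event = (t_event <= cfg.censor_horizon).astype(int)
        time = np.minimum(t_event, cfg.censor_horizon)
        surv = pd.DataFrame({"sample_id": expr.columns, "time": time, "event": event})
        cohorts.append(CohortData(cohort_id=f"cohort{c:02d}", expression=expr,
                                  survival=surv))
    return cohorts


# ------------------------------------------------------------------ CLIP / m6A

def generate_peaks(cfg: SimulationConfig, truth: pd.DataFrame,
                   models: GeneModels, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, dict]:
    """CLIP peaks per sample: significant stop-proximal peaks on bound
    targets, sub-threshold decoys scattered on unbound genes."""
    rows, peak_positions = [], {}
    samples = [f"clip_s{i+1}" for i in range(cfg.n_clip_samples)]
    for row in truth.itertuples():
        t = models.designated_transcript(row.gene_id)
        m1, m2 = t.cds_mature_interval()
        if row.clip_bound:
            centers = []
            for si, s in enumerate(samples):
                if si > 0 and rng.random() >= 0.8:
                    continue
                for _ in range(1 + rng.poisson(1.0)):
                    mc = int(np.clip(m2 + rng.normal(0.0, 25.0), 0, t.mature_length - 1))
                    g = t.mature_to_genomic(mc)
                    centers.append(g)
                    rows.append((t.chrom, max(0, g - 20), g + 20, s, 0, t.strand,
                                 float(rng.uniform(8.5, 64.0)),
                                 float(rng.uniform(5.5, 20.0)), s))
            peak_positions[row.gene_id] = centers
        elif rng.random() < 0.3:  # decoy failing the significance filter
            s = samples[int(rng.integers(0, len(samples)))]
            mc = int(rng.integers(0, t.mature_length))
            g = t.mature_to_genomic(mc)
            if rng.random() < 0.5:
                fold, nlp = float(rng.uniform(1.0, 7.9)), float(rng.uniform(5.5, 12.0))
            else:
                fold, nlp = float(rng.uniform(8.5, 30.0)), float(rng.uniform(0.5, 4.9))
            rows.append((t.chrom, max(0, g - 20), g + 20, s, 0, t.strand, fold, nlp, s))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                        "strand", "fold_enrichment",
                                        "neg_log10_pvalue", "sample_id"])
    peaks["p_value"] = 10.0 ** (-peaks["neg_log10_pvalue"])
    return peaks, peak_positions


def generate_m6a(cfg: SimulationConfig, truth: pd.DataFrame, models: GeneModels,
                 rng: np.random.Generator) -> pd.DataFrame:
    """m6A sites: targets get many stop-proximal exonic sites (count ~25 in
    median), other genes few, with presence scaling with 3'UTR length."""
    rows = []
    for row in truth.itertuples():
        t = models.designated_transcript(row.gene_id)
        _, m2 = t.cds_mature_interval()
        u3 = t.utr3_length
        if row.label in ("target_down", "target_up"):
            k = rng.poisson(25.0)
        else:
            p_any = min(0.85, 0.15 + u3 / 4000.0)
            k = (1 + rng.poisson(1.0 + u3 / 1500.0)) if rng.random() < p_any else 0
        for _ in range(k):
            mc = int(np.clip(m2 + rng.normal(40.0, 120.0), 0, t.mature_length - 1))
            rows.append((t.chrom, t.mature_to_genomic(mc), t.strand))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


# ------------------------------------------------------------------ miRNA / TF

def generate_mirna(cfg: SimulationConfig, truth: pd.DataFrame,
                   rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """miRNA CPM table, 8-database prediction table, family map.

    True interactions preferentially hit CLIP-bound targets; each database
    is an independent noisy view (configurable sensitivity / false-positive
    rate) of the true interaction matrix, so true pairs almost always appear
    in >=2 databases while spurious pairs rarely do.
    """
    mirnas = [f"mir-{i:04d}" for i in range(1, cfg.n_mirnas + 1)]
    lines = [f"line{j+1}" for j in range(cfg.n_cell_lines)]
    expressed = rng.random(cfg.n_mirnas) < 0.5
    cpm = np.where(expressed[:, None],
                   rng.lognormal(math.log(300.0), 0.5, size=(cfg.n_mirnas, cfg.n_cell_lines)),
                   rng.lognormal(math.log(15.0), 0.5, size=(cfg.n_mirnas, cfg.n_cell_lines)))
    expr = pd.DataFrame({
        "mirna_id": np.repeat(mirnas, cfg.n_cell_lines),
        "cell_line": lines * cfg.n_mirnas,
        "cpm": cpm.ravel(),
    })
    bound = truth["clip_bound"].to_numpy()
    p_true = np.where(bound, 0.30, 0.02)
    interacts = rng.random((cfg.n_mirnas, cfg.n_genes)) < p_true[None, :]
    db_names = [f"db{d+1}" for d in range(cfg.n_databases)]
    genes = truth["gene_id"].to_numpy()
    rows = []
    for d, db in enumerate(db_names):
        seen = np.where(interacts,
                        rng.random((cfg.n_mirnas, cfg.n_genes)) < cfg.db_sensitivity,
                        rng.random((cfg.n_mirnas, cfg.n_genes)) < cfg.db_fpr)
        mi, gi = np.nonzero(seen)
        rows.append(pd.DataFrame({"mirna_id": np.array(mirnas)[mi],
                                  "gene_id": genes[gi], "db_name": db}))
    preds = pd.concat(rows, ignore_index=True)
    # one multi-member family among the expressed miRNAs, singletons otherwise
    fam = np.array([f"fam-{m}" for m in mirnas], dtype=object)
    expressed_idx = np.flatnonzero(expressed)
    if len(expressed_idx) >= 8:
        fam[rng.choice(expressed_idx, size=8, replace=False)] = "let7like"
    families = pd.DataFrame({"mirna_id": mirnas, "family": fam})
    return expr, preds, families


def generate_motif_annotation(cfg: SimulationConfig, truth: pd.DataFrame,
                              rng: np.random.Generator) -> pd.DataFrame:
    """TF->gene annotation with an 'E2F-like' family covering target_down
    genes preferentially; all other TFs are label-independent."""
    down = (truth["label"] == "target_down").to_numpy()
    genes = truth["gene_id"].to_numpy()
    rows = []
    for i in range(1, 6):
        cover = np.where(down, rng.random(cfg.n_genes) < 0.8,
                         rng.random(cfg.n_genes) < 0.08)
        rows.append(pd.DataFrame({"tf_id": f"E2F-like-{i}", "gene_id": genes[cover]}))
    for i in range(1, 16):
        cover = rng.random(cfg.n_genes) < 0.1
        rows.append(pd.DataFrame({"tf_id": f"TF{i:02d}", "gene_id": genes[cover]}))
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------------------ top level

def simulate(cfg: SimulationConfig) -> SimulationBundle:
    """Run the whole generator with one seeded RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    truth = _plant_truth(cfg, rng)
    models, seqs = generate_annotation(cfg, truth, rng)
    deg_tables = generate_de_tables(cfg, truth, rng)
    cohorts = generate_cohorts(cfg, truth, rng)
    peaks, peak_positions = generate_peaks(cfg, truth, models, rng)
    m6a = generate_m6a(cfg, truth, models, rng)
    mirna_expr, mirna_preds, families = generate_mirna(cfg, truth, rng)
    tf_annotation = generate_motif_annotation(cfg, truth, rng)
    return SimulationBundle(cfg=cfg, truth=truth, models=models, utr3_seqs=seqs,
                            deg_tables=deg_tables, cohorts=cohorts, peaks=peaks,
                            m6a=m6a, mirna_expr=mirna_expr, mirna_preds=mirna_preds,
                            mirna_families=families, tf_annotation=tf_annotation,
                            peak_positions=peak_positions)


def write_bundle(bundle: SimulationBundle, outdir: str | Path) -> None:
    """Serialize every generated input (and the truth) under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gtf(bundle.models, out / "annotation.gtf")
    write_fasta(bundle.utr3_seqs, out / "utr3.fasta")
    write_tsv(bundle.truth, out / "truth.tsv")
    for e, tbl in enumerate(bundle.deg_tables, start=1):
        write_tsv(tbl, out / f"deg_experiment{e}.tsv")
    cdir = out / "cohorts"
    cdir.mkdir(exist_ok=True)
    for c in bundle.cohorts:
        c.expression.rename_axis("gene_id").reset_index().to_csv(
            cdir / f"{c.cohort_id}_expression.tsv", sep="\t", index=False)
        write_tsv(c.survival, cdir / f"{c.cohort_id}_clinical.tsv")
    pdir = out / "peaks"
    pdir.mkdir(exist_ok=True)
    for sid, grp in bundle.peaks.groupby("sample_id"):
        write_peaks_bed(grp, pdir / f"{sid}.bed")
    write_tsv(bundle.m6a, out / "m6a_sites.tsv")
    write_tsv(bundle.mirna_expr, out / "mirna_expression.tsv")
    write_tsv(bundle.mirna_preds, out / "mirna_predictions.tsv")
    write_tsv(bundle.mirna_families, out / "mirna_families.tsv")
    write_tsv(bundle.tf_annotation, out / "tf_annotation.tsv")
    pos = pd.DataFrame({
        "gene_id": sorted(bundle.peak_positions),
        "peak_centers": [",".join(map(str, bundle.peak_positions[g]))
                         for g in sorted(bundle.peak_positions)],
    })
    write_tsv(pos, out / "planted_peak_centers.tsv")
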