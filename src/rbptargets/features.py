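"""Per-gene 3'UTR regulatory-feature annotation and group comparison.

Covers strand-aware UTR/CDS length decomposition, the per-gene maximum
3'UTR length over isoforms, per-gene m6A counts (maximum exonic site count
over transcripts), an AU-rich-element scanner (AUUUA pentamer in an AU-rich
13-nt window), overlapping IUPAC 4-mer motif densities normalized to
sequence length, and Mann-Whitney group comparison.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModels, TranscriptModel

ARE_PENTAMER = "AUUUA"
ARE_WINDOW = 13
ARE_AU_MIN = 10 / 13


def utr_lengths(model: TranscriptModel) -> tuple[int, int, int]:
    """Exonic (5'UTR, CDS, 3'UTR) lengths of one transcript, strand-aware."""
    return model.utr_lengths()


def max_utr3(transcripts: list) -> int:
    """Maximum 3'UTR length over a gene's transcript models."""
    if not transcripts:
        raise ValueError("need at least one transcript")
    return max(t.utr3_length for t in transcripts)


def m6a_count(gene_id: str, sites: pd.DataFrame, models: GeneModels) -> int:
    """Maximum number of exonic m6A sites over the gene's transcripts.

    Sites falling in introns are not counted; each transcript is scored
    separately and the per-gene maximum is returned.
    """
    ts = models.by_gene[gene_id]
    chroms = {t.chrom for t in ts}
    sub = sites.loc[sites["chrom"].isin(chroms)]
    best = 0
    for t in ts:
        pos = sub.loc[sub["chrom"] == t.chrom, "pos"].to_numpy()
        n = sum(1 for p in pos if t.genomic_to_mature(int(p)) is not None)
        best = max(best, n)
    return best


def _normalize_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if re.search(r"[^ACGU]", seq):
        raise ValueError("sequence contains non-nucleotide characters")
    return seq


def are_scan(utr3_seq: str) -> tuple[bool, int]:
    """ARE call for one 3'UTR: (has_are, overlapping AUUUA pentamer count).

    ``has_are`` requires at least one pentamer whose enclosing 13-nt window
    (4 nt flanks, truncated at sequence ends) is >= 10/13 A/U.
    """
    seq = _normalize_rna(utr3_seq)
    flank = (ARE_WINDOW - len(ARE_PENTAMER)) // 2
    n, has = 0, False
    for m in re.finditer(f"(?={ARE_PENTAMER})", seq):
        n += 1
        i = m.start()
        win = seq[max(0, i - flank): i + len(ARE_PENTAMER) + flank]
        au = sum(c in "AU" for c in win)
        if au / len(win) >= ARE_AU_MIN:
            has = True
    return has, n


def motif_density(seq: str, motifs: list, allow_any_length: bool = False) -> dict:
    """Overlapping per-nt frequency of each IUPAC 4-mer motif in ``seq``."""
    seq = _normalize_rna(seq)
    if len(seq) < 4:
        raise ValueError("sequence shorter than motif length")
    iupac = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U", "R": "AG",
             "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
             "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU"}
    out = {}
    for motif in motifs:
        if len(motif) != 4 and not allow_any_length:
            raise ValueError(f"motif {motif!r} is not a 4-mer")
        pat = "".join(f"[{iupac[c.upper()]}]" for c in motif)
        n = len(re.findall(f"(?={pat})", seq))
        out[motif] = n / (len(seq) - len(motif) + 1)
    return out


def compare_groups(values_a, values_b, alternative: str = "two-sided"
                   ) -> tuple[float, float]:
    """Mann-Whitney U (mid-ranks) of group a vs group b.

    Exact p by enumeration when the pooled sample is small (n <= 12) and
    tie-free, otherwise the tie-corrected normal approximation with
    continuity correction. Fully degenerate input (a single pooled value)
    yields U = n_a*n_b/2 and p = 1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def feature_table(gene_ids: list, models: GeneModels, m6a_sites: pd.DataFrame,
                  utr3_seqs: dict, motifs: list) -> pd.DataFrame:
    """One row per gene: max 3'UTR length, m6A count, ARE flag, motif
    densities of the designated (longest-3'UTR) transcript's 3'UTR."""
    rows = []
    for g in gene_ids:
        t = models.designated_transcript(g)
        seq = utr3_seqs.get(t.transcript_id, "")
        has_are, n_pent = are_scan(seq) if seq else (False, 0)
        dens = (motif_density(seq, motifs) if len(seq) >= 4
                else {m: 0.0 for m in motifs})
        row = {"gene_id": g, "max_utr3_len": models.max_utr3(g),
               "m6a_sites": m6a_count(g, m6a_sites, models),
               "has_are": has_are, "n_are_pentamers": n_pent}
        row.update({f"density_{m}": dens[m] for m in motifs})
        rows.append(row)
    return pd.DataFrame(rows)
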