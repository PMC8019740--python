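"""Readers and writers for the pipeline's on-disk formats.

Annotation travels as GTF (1-based inclusive on disk, converted to 0-based
half-open on read); peaks as BED6+2 with fold enrichment and -log10 p-value
in columns 7-8; everything tabular as TSV with a header row. Sequences use
FASTA via Biopython.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModels, TranscriptModel

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                "fold_enrichment", "neg_log10_pvalue"]


# ---------------------------------------------------------------- annotation

def write_gtf(models: GeneModels, path: str | Path) -> None:
    lines: list[str] = []
    for gene_id in models.gene_ids:
        chrom, gstart, gend = models.gene_span(gene_id)
        strand = models.by_gene[gene_id][0].strand
        lines.append(_gtf_line(chrom, "gene", gstart, gend, strand,
                               f'gene_id "{gene_id}";'))
        for t in sorted(models.by_gene[gene_id], key=lambda t: t.transcript_id):
            attrs = f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}";'
            lines.append(_gtf_line(chrom, "transcript", *t.span, t.strand, attrs))
            for s, e in t.exons:
                lines.append(_gtf_line(chrom, "exon", s, e, t.strand, attrs))
            lines.append(_gtf_line(chrom, "CDS", t.cds_start, t.cds_end, t.strand, attrs))
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_line(chrom: str, feature: str, start: int, end: int, strand: str, attrs: str) -> str:
    # GTF is 1-based inclusive; internal coordinates are 0-based half-open
    return "\t".join([chrom, "rbptargets", feature, str(start + 1), str(end),
                      ".", strand, ".", attrs])


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> GeneModels:
    """Parse a GTF-like annotation into transcript models (0-based half-open)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if feature not in ("exon", "CDS"):
                continue
            d = dict(_ATTR_RE.findall(attrs))
            tid = d["transcript_id"]
            meta[tid] = (d["gene_id"], chrom, strand)
            iv = (int(start) - 1, int(end))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    transcripts = []
    for tid, (gene_id, chrom, strand) in meta.items():
        ex = tuple(sorted(exons[tid]))
        cd = sorted(cds[tid])
        transcripts.append(TranscriptModel(
            transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
            exons=ex, cds_start=cd[0][0], cds_end=cd[-1][1]))
    return GeneModels.from_transcripts(transcripts)


# ---------------------------------------------------------------- sequences

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seqs[k]), id=k, description="") for k in sorted(seqs)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- peaks

def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path, sample_id: str | None = None,
                   p_col: str = "neglog10p", fold_scale: str = "linear") -> pd.DataFrame:
    """Read a BED6+2 peak file into the canonical peak frame.

    ``p_col`` selects the column-8 dialect (raw p-values or -log10 p-values);
    ``fold_scale`` may be ``log2`` when column 7 carries log2 fold enrichment.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS)
    if p_col == "neglog10p":
        df["p_value"] = 10.0 ** (-df["neg_log10_pvalue"])
    elif p_col == "p":
        df["p_value"] = df["neg_log10_pvalue"]
    else:
        raise ValueError(f"unknown p_col dialect: {p_col}")
    if fold_scale == "log2":
        df["fold_enrichment"] = 2.0 ** df["fold_enrichment"]
    elif fold_scale != "linear":
        raise ValueError(f"unknown fold_scale: {fold_scale}")
    df["sample_id"] = sample_id if sample_id is not None else df["name"]
    return df


# ---------------------------------------------------------------- tables

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_deg_tables(paths: Iterable[str | Path]) -> list[pd.DataFrame]:
    return [read_tsv(p) for p in paths]
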