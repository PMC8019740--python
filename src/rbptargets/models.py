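"""Transcript models and strand-aware coordinate arithmetic.

All genomic coordinates are 0-based half-open (BED convention). A
:class:`TranscriptModel` carries its exon chain in genomic order plus the
genomic CDS interval; mature (spliced-transcript) coordinates run 5'->3'
in transcript orientation, so on the minus strand mature position 0 is the
rightmost genomic exonic base.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: exon chain plus genomic CDS interval.

    ``exons`` must be sorted, disjoint, non-empty ``(start, end)`` pairs in
    genomic order; ``cds_start``/``cds_end`` delimit the CDS as a genomic
    interval whose exonic part is contiguous in mature coordinates.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
            raise ValueError(f"{self.transcript_id}: CDS outside exon span")
        # CDS boundaries must themselves be exonic bases
        if self.genomic_to_mature(self.cds_start) is None or self.genomic_to_mature(self.cds_end - 1) is None:
            raise ValueError(f"{self.transcript_id}: CDS boundary not exonic")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _cumlens(self) -> list[int]:
        out, acc = [], 0
        for s, e in self.exons:
            out.append(acc)
            acc += e - s
        return out

    def genomic_to_mature(self, pos: int) -> int | None:
        """Mature coordinate of genomic base ``pos``, or None if intronic/outside."""
        starts = [s for s, _ in self.exons]
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        s, e = self.exons[i]
        if not (s <= pos < e):
            return None
        plus = self._cumlens()[i] + (pos - s)
        if self.strand == "+":
            return plus
        return self.mature_length - 1 - plus

    def mature_to_genomic(self, m: int) -> int:
        """Genomic position of mature coordinate ``m`` (0 <= m < mature_length)."""
        if not 0 <= m < self.mature_length:
            raise IndexError(f"mature coordinate {m} out of range")
        plus = m if self.strand == "+" else self.mature_length - 1 - m
        for (s, e), c in zip(self.exons, self._cumlens()):
            if c <= plus < c + (e - s):
                return s + (plus - c)
        raise AssertionError("unreachable")

    def cds_mature_interval(self) -> tuple[int, int]:
        """Mature-coordinate half-open interval covered by the CDS."""
        if self.strand == "+":
            m1 = self.genomic_to_mature(self.cds_start)
            m2 = self.genomic_to_mature(self.cds_end - 1)
        else:
            m1 = self.genomic_to_mature(self.cds_end - 1)
            m2 = self.genomic_to_mature(self.cds_start)
        assert m1 is not None and m2 is not None
        return m1, m2 + 1

    def utr_lengths(self) -> tuple[int, int, int]:
        """Exonic (5'UTR, CDS, 3'UTR) lengths; introns excluded, strand-aware."""
        m1, m2 = self.cds_mature_interval()
        return m1, m2 - m1, self.mature_length - m2

    @property
    def utr3_length(self) -> int:
        return self.utr_lengths()[2]


@dataclass
class GeneModels:
    """All transcript models of one annotation, grouped by gene."""

    by_gene: dict[str, list[TranscriptModel]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "GeneModels":
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        return cls(by_gene)

    def __iter__(self):
        return iter(self.by_gene.items())

    def __len__(self) -> int:
        return len(self.by_gene)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.by_gene)

    def transcripts(self) -> list[TranscriptModel]:
        return [t for ts in self.by_gene.values() for t in ts]

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """(chrom, start, end) union span of all the gene's transcripts."""
        ts = self.by_gene[gene_id]
        return ts[0].chrom, min(t.span[0] for t in ts), max(t.span[1] for t in ts)

    def designated_transcript(self, gene_id: str) -> TranscriptModel:
        """The gene's transcript with the longest 3'UTR (ties by transcript_id)."""
        return max(self.by_gene[gene_id], key=lambda t: (t.utr3_length, t.transcript_id))

    def max_utr3(self, gene_id: str) -> int:
        """Maximum annotated 3'UTR length over the gene's transcripts."""
        return max(t.utr3_length for t in self.by_gene[gene_id])

    def max_utr3_table(self, gene_ids: Sequence[str] | None = None) -> Mapping[str, int]:
        ids = self.gene_ids if gene_ids is None else gene_ids
        return {g: self.max_utr3(g) for g in ids}
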