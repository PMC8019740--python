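"""Meta-gene profiles: relative site frequencies over 30 bins each of
5'UTR, CDS and 3'UTR in transcript orientation (90 bins total).

A genomic site contributes only when exonic on the gene's designated
transcript; its region and relative position within that region place it
in one bin, and the pooled counts over all genes are normalized to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GeneModels, TranscriptModel

BINS_PER_REGION = 30
N_BINS = 3 * BINS_PER_REGION
REGIONS = ("utr5", "cds", "utr3")


@dataclass
class MetaGeneProfile:
    bins: np.ndarray  # 90 relative frequencies
    n_sites: int
    region_boundaries: tuple = (BINS_PER_REGION, 2 * BINS_PER_REGION)

    @property
    def mode_bin(self) -> int:
        return int(np.argmax(self.bins))

    def to_frame(self) -> pd.DataFrame:
        region = [REGIONS[b // BINS_PER_REGION] for b in range(N_BINS)]
        return pd.DataFrame({"bin": range(N_BINS), "region": region,
                             "frequency": self.bins})


def site_to_bin(site: int, model: TranscriptModel) -> int | None:
    """Bin index in [0, 90) for a genomic position, or None when the site
    is intronic/intergenic or its region is absent from the transcript."""
    m = model.genomic_to_mature(site)
    if m is None:
        return None
    m1, m2 = model.cds_mature_interval()
    bounds = [(0, m1, 0), (m1, m2, BINS_PER_REGION),
              (m2, model.mature_length, 2 * BINS_PER_REGION)]
    for lo, hi, offset in bounds:
        if lo <= m < hi:
            r = (m - lo) / (hi - lo)
            return offset + min(BINS_PER_REGION - 1, int(BINS_PER_REGION * r))
    return None


def aggregate_profile(sites: pd.DataFrame, models: GeneModels,
                      gene_ids: list | None = None,
                      use_midpoint: bool = True) -> MetaGeneProfile:
    """Pooled 90-bin profile of sites/peaks over the designated transcripts.

    ``sites`` needs ``chrom`` plus either ``pos`` or ``start``/``end``
    columns; intervals are represented by their midpoints (set
    ``use_midpoint=False`` to smear each interval over every covered base).
    """
    ids = models.gene_ids if gene_ids is None else list(gene_ids)
    designated = {g: models.designated_transcript(g) for g in ids}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in designated.values():
        by_chrom.setdefault(t.chrom, []).append(t)
    counts = np.zeros(N_BINS)
    n_mapped = 0
    for row in sites.itertuples():
        if hasattr(row, "pos"):
            positions = [int(row.pos)]
        elif use_midpoint:
            positions = [(int(row.start) + int(row.end)) // 2]
        else:
            positions = range(int(row.start), int(row.end))
        for t in by_chrom.get(row.chrom, []):
            for p in positions:
                b = site_to_bin(p, t)
                if b is not None:
                    counts[b] += 1
                    n_mapped += 1
    total = counts.sum()
    freqs = counts / total if total > 0 else counts
    return MetaGeneProfile(bins=freqs, n_sites=n_mapped)
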