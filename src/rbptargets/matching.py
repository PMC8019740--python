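"""3'UTR-length-matched control set construction.

For each target gene, processed in seeded random order, the still-unused
pool gene nearest in log10(length + 1) is selected (greedy, without
replacement). The log scale reflects the heavy right tail of 3'UTR length
distributions; the quality of the match is reported as both groups'
median lengths rather than enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class MatchResult:
    matched_ids: set
    target_median_len: float
    matched_median_len: float
    seed: int


def match_by_length(targets: set, pool: set, lengths: dict, seed: int) -> MatchResult:
    """Select ``len(targets)`` pool genes matching the targets' lengths."""
    targets, pool = sorted(targets), sorted(pool)
    if len(pool) < len(targets):
        raise ValueError(f"pool ({len(pool)}) smaller than targets ({len(targets)})")
    missing = [g for g in list(targets) + pool if g not in lengths]
    if missing:
        raise KeyError(f"no length for gene(s): {missing[:5]}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    pool_ids = np.array(pool, dtype=object)
    pool_log = np.array([math.log10(lengths[g] + 1) for g in pool])
    used = np.zeros(len(pool), dtype=bool)
    matched: list = []
    for i in order:
        tlog = math.log10(lengths[targets[i]] + 1)
        free = np.flatnonzero(~used)
        j = free[int(np.argmin(np.abs(pool_log[free] - tlog)))]
        used[j] = True
        matched.append(pool_ids[j])
    return MatchResult(
        matched_ids=set(matched),
        target_median_len=float(np.median([lengths[g] for g in targets])),
        matched_median_len=float(np.median([lengths[g] for g in matched])),
        seed=seed)
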