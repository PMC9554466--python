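"""Levins' niche breadth and its abundance-weighted community mean (Bcom).

Levins' B treats the samples as resource states: for a taxon whose reads
are distributed across samples with proportions ``p_j``,

    B = 1 / sum_j p_j**2

so B ranges from 1 (all reads in one sample) to S (uniform use of all S
samples). A community-level value, Bcom, is the abundance-weighted mean of
the B values of the taxa present in a sample — communities dominated by
broad-niche generalists score high.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import CommunityTable

__all__ = ["levins_b", "niche_breadth", "community_bcom"]


def levins_b(use: np.ndarray) -> float:
    """Levins' niche breadth of one taxon from its across-sample use vector."""
    use = np.asarray(use, dtype=float)
    total = use.sum()
    if total <= 0:
        raise ValueError("use vector has no nonzero entries")
    p = use / total
    return float(1.0 / np.sum(p**2))


def niche_breadth(table: CommunityTable) -> pd.Series:
    """Per-taxon Levins' B over the table's samples.

    Taxa with zero total count get NaN (no niche to measure).
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
        b = 1.0 / np.nansum(p**2, axis=0)
    b[totals == 0] = np.nan
    return pd.Series(b, index=table.taxon_ids, name="levins_b")


def community_bcom(table: CommunityTable, b: pd.Series | None = None) -> pd.Series:
    """Abundance-weighted mean B per sample.

    Weights are the within-sample relative abundances renormalised over the
    taxa present in that sample; every present taxon must have a B value.
    """
    if b is None:
        b = niche_breadth(table)
    b = b.reindex(table.taxon_ids)
    counts = table.counts.astype(float)
    out = np.empty(table.n_samples)
    bvals = b.to_numpy(float)
    for i in range(table.n_samples):
        present = counts[i] > 0
        if not present.any():
            raise ValueError(f"empty sample: {table.sample_ids[i]}")
        if np.any(np.isnan(bvals[present])):
            missing = [t for t, m, pr in zip(table.taxon_ids, np.isnan(bvals), present) if m and pr]
            raise ValueError(f"no B value for present taxa: {missing[:5]}")
        w = counts[i, present]
        out[i] = np.average(bvals[present], weights=w)
    return pd.Series(out, index=table.sample_ids, name="bcom")
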