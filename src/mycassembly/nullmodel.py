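"""Abundance-based null communities and the standardized beta-deviation.

The null model randomizes each local community (sample) while preserving
its observed species richness and total abundance: a sample that held
``S_k`` taxa and ``N_k`` reads is rebuilt by (a) drawing ``S_k`` distinct
taxa from the regional pool without replacement, with probability
proportional to regional (column-sum) abundance, and (b) allocating the
``N_k`` reads among the drawn taxa in proportion to their regional
abundances, with every drawn taxon guaranteed at least one read.

The beta-deviation of a sample pair is the standardized effect size of its
Bray-Curtis dissimilarity against the null ensemble:

    deviation = (beta_obs - mean(beta_null)) / sd(beta_null)

Strongly positive deviations indicate dispersal limitation or heterogeneous
selection; strongly negative ones indicate homogenizing dispersal or
homogeneous selection; deviations near zero are consistent with stochastic
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import CommunityTable
from .distances import DistanceMatrix

__all__ = ["BetaDeviationResult", "generate_null_community", "beta_deviation"]


@dataclass
class BetaDeviationResult:
    """Per-pair observed beta, null mean/SD, and standardized deviation."""

    pairs: pd.DataFrame  # sample_a, sample_b, beta_obs, null_mean, null_sd, deviation
    reps: int
    seed: int | None
    labels: list[str]

    @property
    def deviations(self) -> np.ndarray:
        return self.pairs["deviation"].to_numpy(float)

    def deviation_matrix(self) -> DistanceMatrix:
        """Deviations folded back into a labelled symmetric matrix."""
        return DistanceMatrix(
            squareform(self.deviations, checks=False), list(self.labels),
            kind="beta_deviation",
        )


def _null_sample(pool_prob: np.ndarray, richness: int, total: int,
                 rng: np.random.Generator, mode: str) -> np.ndarray:
    """One null local community: ``richness`` taxa, ``total`` reads."""
    n_taxa = len(pool_prob)
    if richness > np.count_nonzero(pool_prob):
        raise ValueError(
            f"sample richness {richness} exceeds the {np.count_nonzero(pool_prob)} "
            "taxa available in the regional pool"
        )
    drawn = rng.choice(n_taxa, size=richness, replace=False, p=pool_prob)
    p = pool_prob[drawn]
    p = p / p.sum()
    out = np.zeros(n_taxa, dtype=np.int64)
    if mode == "seeded":
        # 1 read per drawn taxon up front, remainder multinomial: exact
        # constraint satisfaction without rejection.
        out[drawn] = 1 + rng.multinomial(total - richness, p)
    elif mode == "rejection":
        while True:
            alloc = rng.multinomial(total, p)
            if np.all(alloc > 0):
                out[drawn] = alloc
                break
    else:
        raise ValueError(f"unknown allocation mode {mode!r}")
    return out


def generate_null_community(table: CommunityTable, seed: int | None = None,
                            mode: str = "seeded", pool: np.ndarray | None = None,
                            rng: np.random.Generator | None = None) -> CommunityTable:
    """One null replicate of ``table`` (per-sample richness and totals preserved).

    ``mode`` selects how reads are allocated among the drawn taxa:
    ``"seeded"`` (default) gives every drawn taxon one read then distributes
    the remainder multinomially; ``"rejection"`` redraws the full multinomial
    until no drawn taxon is empty. ``pool`` optionally supplies the regional
    abundances (one weight per taxon) instead of the table's column sums.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if pool is None:
        pool = table.counts.sum(axis=0).astype(float)
    else:
        pool = np.asarray(pool, dtype=float)
        if pool.shape != (table.n_taxa,):
            raise ValueError("pool must have one weight per taxon")
    pool_prob = pool / pool.sum()
    richness = np.count_nonzero(table.counts, axis=1)
    if np.any(richness < 1):
        empty = [s for s, r in zip(table.sample_ids, richness) if r < 1]
        raise ValueError(f"sample(s) with zero richness: {empty}")
    totals = table.depth
    out = np.empty_like(table.counts)
    for k in range(table.n_samples):
        out[k] = _null_sample(pool_prob, int(richness[k]), int(totals[k]), rng, mode)
    return CommunityTable(out, list(table.sample_ids), list(table.taxon_ids))


def beta_deviation(table: CommunityTable, reps: int = 999, seed: int | None = None,
                   mode: str = "seeded", pool: np.ndarray | None = None) -> BetaDeviationResult:
    """Standardized beta-deviation of every sample pair against the null ensemble.

    The null mean and SD per pair are taken over ``reps`` independent null
    replicates (sample SD, n-1). Replicates use independent substreams
    spawned from the master seed, so results are reproducible regardless of
    execution order. Pairs whose null SD is zero get NaN deviations (with
    the pair retained so the output shape is stable).

    By default the regional pool is the table's own column sums (the field
    convention); ``pool`` overrides it, e.g. with independently known
    regional abundances. Estimating the pool from the data conditions the
    null on the single observed realisation and deflates deviations
    slightly — on null data the procedure scores a small negative mean
    rather than exactly zero.
    """
    if reps < 99:
        raise ValueError("reps must be >= 99 for a stable null mean/SD")
    obs = pdist(table.counts.astype(float), metric="braycurtis")
    n_pairs = len(obs)
    acc = np.zeros(n_pairs)
    acc2 = np.zeros(n_pairs)
    bmin = np.full(n_pairs, np.inf)
    bmax = np.full(n_pairs, -np.inf)
    streams = np.random.SeedSequence(seed).spawn(reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        null = generate_null_community(table, rng=rng, mode=mode, pool=pool)
        b = pdist(null.counts.astype(float), metric="braycurtis")
        acc += b
        acc2 += b * b
        np.minimum(bmin, b, out=bmin)
        np.maximum(bmax, b, out=bmax)
    mean = acc / reps
    var = (acc2 - reps * mean**2) / (reps - 1)
    # a constant null ensemble has zero SD; detect it exactly via the range
    # (the accumulator formula alone suffers float cancellation there)
    degenerate = bmax == bmin
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[degenerate] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = (obs - mean) / sd
    dev[degenerate] = np.nan
    n = table.n_samples
    ii, jj = np.triu_indices(n, k=1)
    pairs = pd.DataFrame(
        {
            "sample_a": [table.sample_ids[j] for j in jj],
            "sample_b": [table.sample_ids[i] for i in ii],
            "beta_obs": obs,
            "null_mean": mean,
            "null_sd": sd,
            "deviation": dev,
        }
    )
    return BetaDeviationResult(pairs=pairs, reps=reps, seed=seed,
                               labels=list(table.sample_ids))
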