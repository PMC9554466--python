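"""Sloan neutral community model: occurrence frequency vs. mean abundance.

Under neutral immigration from a regional pool, the long-run local relative
abundance of a taxon with regional mean relative abundance ``p`` follows a
Beta(N*m*p, N*m*(1-p)) distribution, where ``N`` is the local community
size (here, the rarefied read depth) and ``m`` the immigration rate. The
probability of detecting the taxon — its expected occurrence frequency —
is the upper tail of that Beta above the detection limit ``d``:

    freq(p) = 1 - I_d(N*m*p, N*m*(1-p))

with ``I`` the regularized incomplete beta function and ``d = 1/N`` by
default (one read at the rarefied depth). ``m`` is estimated by least
squares on observed frequencies; R^2 measures how much of the frequency-
abundance relationship neutrality explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tables import CommunityTable

__all__ = ["NCMFit", "sloan_expected_frequency", "fit_ncm"]


@dataclass
class NCMFit:
    m: float
    N: int
    r2: float
    d: float
    taxa: pd.DataFrame  # taxon_id, p, freq_obs, freq_pred, bound_lo, bound_hi
    n_taxa: int
    warning: str | None = None

    def to_dict(self) -> dict:
        return {"m": self.m, "R2": self.r2, "N": self.N, "d": self.d,
                "n_taxa": self.n_taxa, "warning": self.warning}


def sloan_expected_frequency(p, N: float, m: float, d: float | None = None):
    """Expected occurrence frequency of a taxon under the neutral model."""
    p = np.asarray(p, dtype=float)
    if d is None:
        d = 1.0 / N
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundance p must be in (0, 1)")
    if N < 1:
        raise ValueError("community size N must be >= 1")
    if not (0 < m <= 1):
        raise ValueError("migration rate m must be in (0, 1]")
    if not (0 < d < 1):
        raise ValueError("detection limit d must be in (0, 1)")
    nm = N * m
    out = 1.0 - special.betainc(nm * p, nm * (1.0 - p), d)
    return float(out) if out.ndim == 0 else out


def _prediction_bounds(p: np.ndarray, N: float, m: float, d: float,
                       n_samples: int, level: float = 0.95):
    """Binomial prediction band around the fitted frequency curve."""
    freq = sloan_expected_frequency(p, N, m, d)
    lo, hi = stats.binom.interval(level, n_samples, freq)
    return lo / n_samples, hi / n_samples


def fit_ncm(table: CommunityTable, d: float | None = None,
            N: int | None = None, pool_p: np.ndarray | None = None,
            n_starts: tuple[float, ...] = (0.01, 0.1, 0.5)) -> NCMFit:
    """Fit the neutral model to a rarefied community table.

    Per taxon, the observed frequency is the fraction of samples with a
    nonzero count and ``p`` the mean relative abundance; ``m`` minimizes
    the sum of squared frequency residuals (bounded scalar least squares,
    multi-start). Requires equal sample depths (a rarefied table) and at
    least 10 taxa with frequency strictly between 0 and 1.

    Passing ``N`` explicitly skips the equal-depth check and fixes the
    community size (for sensitivity analyses on unrarefied or
    model-generated tables whose row sums only approximate N). Passing
    ``pool_p`` supplies known regional relative abundances per taxon
    instead of estimating them from the table — note that estimating p
    from the same table that provides the occurrence frequencies biases
    m upward, because per-taxon sampling noise enters both axes with
    positive correlation.
    """
    depths = table.depth
    if N is None:
        if len(set(depths.tolist())) != 1:
            raise ValueError("fit_ncm requires a rarefied table (equal sample depths)")
        N = int(depths[0])
    if N < 1:
        raise ValueError("empty samples")
    if d is None:
        d = 1.0 / N
    if pool_p is not None:
        p = np.asarray(pool_p, dtype=float)
        if p.shape != (table.n_taxa,):
            raise ValueError("pool_p must have one entry per taxon")
    else:
        rowsum = np.where(depths > 0, depths, 1)
        p = (table.counts / rowsum[:, None]).mean(axis=0)
    freq_obs = (table.counts > 0).mean(axis=0)
    usable = (p > 0) & (p < 1)
    interior = usable & (freq_obs > 0) & (freq_obs < 1)
    if interior.sum() < 10:
        raise ValueError(
            "degenerate occupancy: need >= 10 taxa with occurrence frequency "
            "strictly between 0 and 1"
        )
    p_fit = p[usable]
    f_fit = freq_obs[usable]

    def sse(log_m: float) -> float:
        pred = sloan_expected_frequency(p_fit, N, np.exp(log_m), d)
        return float(np.sum((f_fit - pred) ** 2))

    best = None
    for m0 in n_starts:
        res = optimize.minimize_scalar(
            sse, bounds=(np.log(1e-6), 0.0), method="bounded",
            options={"xatol": 1e-8},
        )
        # minimize_scalar(bounded) ignores the start; multi-start retained via
        # a local refinement around each m0 for severely multimodal surfaces
        local = optimize.minimize_scalar(
            sse,
            bounds=(max(np.log(1e-6), np.log(m0) - 2), min(0.0, np.log(m0) + 2)),
            method="bounded", options={"xatol": 1e-8},
        )
        for cand in (res, local):
            if best is None or cand.fun < best.fun:
                best = cand
    m_hat = float(np.exp(best.x))
    pred = sloan_expected_frequency(p_fit, N, m_hat, d)
    ss_res = float(np.sum((f_fit - pred) ** 2))
    ss_tot = float(np.sum((f_fit - f_fit.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    lo, hi = _prediction_bounds(p_fit, N, m_hat, d, table.n_samples)
    taxa = pd.DataFrame(
        {
            "taxon_id": [t for t, u in zip(table.taxon_ids, usable) if u],
            "p": p_fit,
            "freq_obs": f_fit,
            "freq_pred": pred,
            "bound_lo": lo,
            "bound_hi": hi,
        }
    )
    warning = None
    if r2 < 0.3:
        warning = ("R2 < 0.3: the frequency-abundance relationship is weak; "
                   "the estimated migration rate m is unreliable")
    return NCMFit(m=m_hat, N=N, r2=r2, d=d, taxa=taxa,
                  n_taxa=int(usable.sum()), warning=warning)
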