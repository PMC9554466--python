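"""Multiple regression on distance matrices (MRM), forward selection,
two-set variation partitioning (VPA), and hierarchical partitioning.

MRM regresses an unfolded (lower-triangle) response distance matrix on one
or more unfolded predictor matrices by OLS. Because the n(n-1)/2 pairs are
not independent, significance comes from permuting the *sample labels* of
the response matrix — rows and columns jointly — and refitting, which
preserves the distance-matrix dependence structure (999 permutations,
+1-corrected p, by default).

Variation partitioning splits the full-model R^2 into pure-spatial,
pure-environmental and shared fractions; hierarchical partitioning assigns
each predictor group an independent contribution, the average R^2 increase
over all orders in which the group can enter the model. Shared fractions
can be negative (a suppression effect) and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix

__all__ = [
    "MRMFit",
    "VPAResult",
    "HPResult",
    "unfold",
    "refold",
    "mrm_fit",
    "forward_select",
    "vpa_two_sets",
    "hierarchical_partition",
]


def unfold(d: DistanceMatrix) -> np.ndarray:
    """Lower-triangle pair vector in condensed order."""
    return d.condensed()


def refold(vec: np.ndarray, labels: list[str], kind: str = "generic") -> DistanceMatrix:
    """Inverse of :func:`unfold`."""
    return DistanceMatrix(squareform(np.asarray(vec, float), checks=False),
                          list(labels), kind=kind)


@dataclass
class MRMFit:
    coefficients: pd.Series       # intercept + one per predictor
    r2: float
    coef_p: pd.Series             # permutation p per predictor
    model_p: float                # permutation p of R^2
    permutations: int
    seed: int | None
    n_pairs: int
    predictor_names: list[str]


def _design(response: DistanceMatrix, predictors: dict[str, DistanceMatrix],
            check_rank: bool = True):
    y = response.condensed()
    names = list(predictors.keys())
    cols = []
    for name in names:
        predictors[name].align(response)
        cols.append(predictors[name].condensed())
    X = np.column_stack([np.ones_like(y)] + cols)
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least 2 more pairs than predictors")
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: predictors {names} are collinear "
            "(or constant) on the pair scale"
        )
    return y, X, names


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def mrm_fit(response: DistanceMatrix, predictors: dict[str, DistanceMatrix],
            permutations: int = 999, seed: int | None = None) -> MRMFit:
    """OLS of an unfolded response matrix on unfolded predictor matrices.

    Coefficient p-values are the +1-corrected fraction of label
    permutations whose |coefficient| meets or exceeds the observed one; the
    model p does the same for R^2.
    """
    y, X, names = _design(response, predictors)
    pinv = np.linalg.pinv(X)
    coef = pinv @ y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    resid = y - X @ coef
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0

    coef_ge = np.zeros(len(names))
    r2_ge = 0
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = response.n
        full = response.values
        perm_y = np.empty((len(y), permutations))
        for b in range(permutations):
            perm = rng.permutation(n)
            perm_y[:, b] = squareform(full[np.ix_(perm, perm)], checks=False)
        coef_b = pinv @ perm_y                       # (k+1) x B
        resid_b = perm_y - X @ coef_b
        # permutation preserves the multiset of y values, so SStot is unchanged
        r2_b = 1.0 - (resid_b**2).sum(axis=0) / ss_tot if ss_tot > 0 else np.zeros(permutations)
        coef_ge = (np.abs(coef_b[1:]) >= np.abs(coef[1:])[:, None]).sum(axis=1)
        r2_ge = int((r2_b >= r2).sum())
    denom = permutations + 1
    coef_p = pd.Series((coef_ge + 1) / denom, index=names) if permutations > 0 \
        else pd.Series(np.nan, index=names)
    model_p = (r2_ge + 1) / denom if permutations > 0 else float("nan")
    return MRMFit(
        coefficients=pd.Series(coef, index=["intercept"] + names),
        r2=r2,
        coef_p=coef_p,
        model_p=float(model_p),
        permutations=permutations,
        seed=seed,
        n_pairs=len(y),
        predictor_names=names,
    )


def forward_select(response: DistanceMatrix, candidates: dict[str, DistanceMatrix],
                   alpha: float = 0.05, permutations: int = 999,
                   seed: int | None = None) -> tuple[list[str], MRMFit | None]:
    """Greedy forward selection of predictor matrices until none qualifies.

    At each step the candidate giving the largest R^2 increase enters,
    provided its coefficient's permutation p is below ``alpha``. Ties are
    broken by candidate name so the procedure is deterministic given the
    seed. Returns the selected names and the final fit (None if the
    selection is empty).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rng = np.random.SeedSequence(seed)
    selected: list[str] = []
    current_r2 = 0.0
    final: MRMFit | None = None
    remaining = sorted(candidates.keys())
    step = 0
    while remaining:
        best_name, best_fit, best_gain = None, None, -np.inf
        for name in remaining:
            preds = {k: candidates[k] for k in selected + [name]}
            sub_seed = int(rng.spawn(1)[0].generate_state(1)[0] % (2**31))
            fit = mrm_fit(response, preds, permutations=permutations, seed=sub_seed)
            gain = fit.r2 - current_r2
            if fit.coef_p[name] < alpha and gain > best_gain + 1e-15:
                best_name, best_fit, best_gain = name, fit, gain
        if best_name is None:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current_r2 = best_fit.r2
        final = best_fit
        step += 1
    return selected, final


@dataclass
class VPAResult:
    """Two-set variation partitioning of the response variance."""

    pure_space: float
    pure_env: float
    shared: float
    unexplained: float
    r2_full: float
    r2_space: float
    r2_env: float

    def fractions(self) -> dict[str, float]:
        return {
            "pure_space": self.pure_space,
            "pure_env": self.pure_env,
            "shared": self.shared,
            "unexplained": self.unexplained,
        }


def vpa_two_sets(response: DistanceMatrix, space_set: dict[str, DistanceMatrix],
                 env_set: dict[str, DistanceMatrix]) -> VPAResult:
    """Partition response variance into pure space, pure environment, shared.

    ``pure_space = R2_full - R2_env``; ``pure_env = R2_full - R2_space``;
    ``shared = R2_space + R2_env - R2_full`` (may be negative);
    ``unexplained = 1 - R2_full``.
    """
    if not space_set or not env_set:
        raise ValueError("both predictor sets must be nonempty")
    overlap = set(space_set) & set(env_set)
    if overlap:
        raise ValueError(f"predictor name(s) in both sets: {sorted(overlap)}")
    # the joint design may be deliberately collinear (fully shared
    # variation); lstsq handles the rank deficiency, so R^2 is well defined
    y, X_full, _ = _design(response, {**space_set, **env_set}, check_rank=False)
    r2_full = _ols_r2(y, X_full)
    _, X_s, _ = _design(response, space_set)
    r2_space = _ols_r2(y, X_s)
    _, X_e, _ = _design(response, env_set)
    r2_env = _ols_r2(y, X_e)
    return VPAResult(
        pure_space=r2_full - r2_env,
        pure_env=r2_full - r2_space,
        shared=r2_space + r2_env - r2_full,
        unexplained=1.0 - r2_full,
        r2_full=r2_full,
        r2_space=r2_space,
        r2_env=r2_env,
    )


@dataclass
class HPResult:
    """Independent contribution of each predictor group to the full R^2."""

    contributions: dict[str, float]
    r2_full: float


def hierarchical_partition(response: DistanceMatrix,
                           groups: dict[str, dict[str, DistanceMatrix]]) -> HPResult:
    """Exact hierarchical partitioning over predictor groups (<= 5 groups).

    The independent contribution of group g is its R^2 increment averaged
    over all orders in which g can enter the model, computed exactly via
    the subset-average (Shapley) formulation over all 2^(k-1) subsets not
    containing g. Contributions sum to the full-model R^2.
    """
    names = list(groups.keys())
    k = len(names)
    if k < 1:
        raise ValueError("need at least one group")
    if k > 5:
        raise ValueError("more than 5 groups: merge related predictors into "
                         "coarser groups (2^k subset fits required)")
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for combo in combinations(names, size):
            preds: dict[str, DistanceMatrix] = {}
            for g in combo:
                preds.update(groups[g])
            y, X, _ = _design(response, preds)
            r2_cache[frozenset(combo)] = _ols_r2(y, X)
    contributions: dict[str, float] = {}
    for g in names:
        others = [x for x in names if x != g]
        total = 0.0
        for size in range(0, k):
            for combo in combinations(others, size):
                s = frozenset(combo)
                weight = factorial(size) * factorial(k - size - 1) / factorial(k)
                total += weight * (r2_cache[s | {g}] - r2_cache[s])
        contributions[g] = total
    return HPResult(contributions=contributions, r2_full=r2_cache[frozenset(names)])
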