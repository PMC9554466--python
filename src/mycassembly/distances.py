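"""Pairwise-distance machinery: Bray-Curtis, geographic and environmental
distances, Mantel tests, PERMANOVA, distance-decay regression, and NMDS.

All matrices are carried as :class:`DistanceMatrix` — a labelled symmetric
matrix with zero diagonal — so that downstream matrix regressions can check
sample alignment instead of trusting positional order. Mantel and PERMANOVA
inference is delegated to scikit-bio; the distance-decay regression (DDR)
is an ordinary least-squares fit of compositional similarity (1 - Bray-
Curtis) against geographic distance over all sample pairs, with an optional
permutation p-value that respects the pairwise dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats

import skbio
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova

from .tables import CommunityTable, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "DDRFit",
    "bray_curtis",
    "geographic_distance",
    "env_distance",
    "single_covariate_distance",
    "mantel",
    "permanova",
    "ddr_fit",
    "nmds_coordinates",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with aligned sample labels."""

    values: np.ndarray
    labels: list[str]
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric (tol 1e-12)")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.labels = [str(x) for x in self.labels]

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format (sample_a, sample_b, value), lower triangle."""
        ii, jj = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "sample_a": [self.labels[j] for j in jj],
                "sample_b": [self.labels[i] for i in ii],
                "value": self.values[ii, jj],
            }
        )

    def align(self, other: "DistanceMatrix") -> None:
        if self.labels != other.labels:
            raise ValueError("distance matrices have mismatched sample labels")

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        """Restrict to ``labels`` (order preserved as given)."""
        index = {s: i for i, s in enumerate(self.labels)}
        missing = [s for s in labels if s not in index]
        if missing:
            raise ValueError(f"unknown label(s): {missing[:5]}")
        rows = [index[s] for s in labels]
        return DistanceMatrix(self.values[np.ix_(rows, rows)], list(labels),
                              kind=self.kind)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    BC(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y).
    """
    if np.any(table.depth == 0):
        zero = [s for s, d in zip(table.sample_ids, table.depth) if d == 0]
        raise ValueError(f"zero-depth sample(s): {zero}")
    d = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(d), list(table.sample_ids), kind="bray_curtis")


def geographic_distance(meta: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distance in km, spherical Earth R = 6371 km."""
    df = meta.frame
    if df[["lat", "lon"]].isna().any(axis=None):
        bad = df.loc[df[["lat", "lon"]].isna().any(axis=1), "sample_id"].tolist()
        raise ValueError(f"missing coordinates for sample(s): {bad}")
    lat = np.radians(df["lat"].to_numpy(float))
    lon = np.radians(df["lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return DistanceMatrix(km, meta.sample_ids, kind="geographic_km")


def _zscore(x: np.ndarray, names) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    bad = [n for n, s in zip(names, sd) if s == 0]
    if bad:
        raise ValueError(f"zero-variance covariate(s), cannot standardize: {bad}")
    return (x - x.mean(axis=0)) / sd


def env_distance(covariates: pd.DataFrame, kind: str = "env_euclidean") -> DistanceMatrix:
    """Euclidean distance on z-scored covariates (each mean 0, SD 1)."""
    if covariates.shape[1] < 1:
        raise ValueError("need at least one covariate")
    z = _zscore(covariates.to_numpy(float), covariates.columns)
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(d, covariates.index.astype(str).tolist(), kind=kind)


def single_covariate_distance(covariates: pd.DataFrame) -> dict[str, DistanceMatrix]:
    """One standardized Euclidean distance matrix per covariate column."""
    return {
        name: env_distance(covariates[[name]], kind=f"env:{name}")
        for name in covariates.columns
    }


def mantel(a: DistanceMatrix, b: DistanceMatrix, permutations: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """Mantel test: Pearson r between unfolded triangles, permutation p.

    The p-value permutes one matrix's rows and columns jointly (two-sided,
    +1-corrected), preserving the matrix dependence structure.
    """
    a.align(b)
    if a.n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    r, p, _ = _skbio_mantel(
        a.to_skbio(), b.to_skbio(), method="pearson",
        permutations=permutations, alternative="two-sided", seed=seed,
    )
    return float(r), float(p)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    permutations: int


def permanova(d: DistanceMatrix, groups, permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """PERMANOVA: pseudo-F of among- vs within-group squared distances.

    ``groups`` is a sequence of group labels aligned to ``d.labels``. R^2 is
    the among-group fraction of the total sum of squared distances.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != d.n:
        raise ValueError("group labels do not match distance matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        single = labels[counts < 2].tolist()
        raise ValueError(f"singleton group(s): {single}")
    res = _skbio_permanova(d.to_skbio(), groups, permutations=permutations, seed=seed)
    f = float(res["test statistic"])
    n, k = d.n, len(labels)
    # F = (SSA/(k-1)) / (SSW/(n-k))  =>  R2 = SSA/SST from F
    r2 = f * (k - 1) / (f * (k - 1) + (n - k))
    return PermanovaResult(pseudo_f=f, r2=float(r2), p_value=float(res["p-value"]),
                           permutations=permutations)


@dataclass
class DDRFit:
    """Distance-decay regression of similarity (1 - Bray-Curtis) on km."""

    slope: float
    intercept: float
    r2: float
    p_value: float          # permutation p (Mantel-style), NaN if not requested
    p_value_ols: float      # naive analytic p, pairs treated as independent
    n_pairs: int
    slope_se: float = field(default=float("nan"))


def ddr_fit(similarity: DistanceMatrix | np.ndarray, geo: DistanceMatrix,
            permutations: int = 0, seed: int | None = None) -> DDRFit:
    """OLS of pairwise similarity against geographic distance.

    ``similarity`` may be a DistanceMatrix of dissimilarities from which
    similarity is taken as 1 - value, or a precomputed condensed vector of
    similarities. The slope is per km. Because pairs sharing a sample are
    not independent, the analytic OLS p is optimistic; when
    ``permutations`` > 0 a label-permutation p is computed as well.
    """
    if isinstance(similarity, DistanceMatrix):
        similarity.align(geo)
        sim = 1.0 - similarity.condensed()
    else:
        sim = np.asarray(similarity, dtype=float)
    dist = geo.condensed()
    if len(sim) != len(dist):
        raise ValueError("similarity and distance pair vectors differ in length")
    if len(dist) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(dist) == 0:
        raise ValueError("zero variance in geographic distance")
    ls = stats.linregress(dist, sim)
    p_perm = float("nan")
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = geo.n
        full_sim = squareform(sim, checks=False)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            s_perm = squareform(full_sim[np.ix_(perm, perm)], checks=False)
            b = stats.linregress(dist, s_perm).slope
            if abs(b) >= abs(ls.slope):
                count += 1
        p_perm = (count + 1) / (permutations + 1)
    return DDRFit(
        slope=float(ls.slope),
        intercept=float(ls.intercept),
        r2=float(ls.rvalue**2),
        p_value=p_perm,
        p_value_ols=float(ls.pvalue),
        n_pairs=len(dist),
        slope_se=float(ls.stderr),
    )


def nmds_coordinates(d: DistanceMatrix, seed: int | None = None) -> pd.DataFrame:
    """2-D non-metric multidimensional scaling coordinates for plotting.

    Stress-minimizing embedding (Kruskal NMDS) via scikit-learn, seeded.
    """
    from sklearn.manifold import MDS

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                  random_state=seed, n_init=4, normalized_stress="auto")
        coords = mds.fit_transform(d.values)
    return pd.DataFrame(coords, index=d.labels, columns=["NMDS1", "NMDS2"])
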