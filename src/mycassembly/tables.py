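"""Community tables, sample metadata, and the pre-analysis filters.

This module owns the two central data containers of the pipeline — an
ASV-by-sample count table (:class:`CommunityTable`) and per-sample metadata
(:class:`SampleMetadata`) — plus the standard preprocessing steps applied
before any assembly inference: discarding very-low-count ASVs, rarefying
every sample to a common read depth, converting to relative abundance,
deriving the aridity covariate from precipitation and evapotranspiration,
and pruning collinear predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "CollinearityResult",
    "read_community_table",
    "write_community_table",
    "filter_low_count_taxa",
    "rarefy",
    "relative_abundance",
    "derive_aridity",
    "collinearity_prune",
]


class TableError(ValueError):
    """Raised for malformed or inconsistent community tables."""


@dataclass
class CommunityTable:
    """Integer count matrix, samples x taxa, with aligned identifiers.

    Attributes
    ----------
    counts
        Non-negative integer matrix of shape ``(n_samples, n_taxa)``.
    sample_ids
        Ordered, unique sample identifiers (rows of ``counts``).
    taxon_ids
        Ordered, unique taxon identifiers (columns of ``counts``).
    warning
        Optional flag set by operations that return a degenerate table
        (e.g. all taxa filtered out).
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix (samples x taxa)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise TableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise TableError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise TableError(f"duplicate {name} ID(s): {sorted(dupes)}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        """Per-sample read totals (row sums)."""
        return self.counts.sum(axis=1)

    def subset_taxa(self, taxa: Sequence[str]) -> "CommunityTable":
        """Return a new table restricted to ``taxa`` (order preserved as given)."""
        index = {t: j for j, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise TableError(f"unknown taxon ID(s): {missing[:5]}")
        cols = [index[t] for t in taxa]
        return CommunityTable(self.counts[:, cols], list(self.sample_ids), list(taxa))

    def subset_samples(self, samples: Sequence[str]) -> "CommunityTable":
        """Return a new table restricted to ``samples`` (order preserved as given)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise TableError(f"unknown sample ID(s): {missing[:5]}")
        rows = [index[s] for s in samples]
        return CommunityTable(self.counts[rows, :], list(samples), list(self.taxon_ids))

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x taxa DataFrame view."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


@dataclass
class SampleMetadata:
    """Per-sample coordinates, vegetation type, and named covariates.

    ``frame`` must contain columns ``sample_id``, ``site_id``, ``lat``,
    ``lon`` and ``vegetation_type``; any further numeric columns are treated
    as environmental / plant covariates. ``plant_composition`` optionally
    holds a plant species abundance table aligned to the same samples.
    """

    frame: pd.DataFrame
    plant_composition: CommunityTable | None = None

    REQUIRED = ("sample_id", "site_id", "lat", "lon", "vegetation_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise TableError(f"metadata missing required column(s): {missing}")
        dupes = _duplicates(self.frame["sample_id"].astype(str))
        if dupes:
            raise TableError(f"duplicate sample_id(s) in metadata: {sorted(dupes)}")
        lat = self.frame["lat"].to_numpy(float)
        lon = self.frame["lon"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise TableError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise TableError("longitude outside [-180, 180]")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].astype(str).tolist()

    def covariates(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric covariate matrix indexed by sample_id."""
        df = self.frame.set_index("sample_id")
        if names is None:
            names = [
                c
                for c in df.columns
                if c not in ("site_id", "lat", "lon", "vegetation_type")
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        return df[list(names)].astype(float)

    def aligned_to(self, table: CommunityTable) -> "SampleMetadata":
        """Reorder metadata rows to the sample order of ``table``."""
        df = self.frame.set_index(self.frame["sample_id"].astype(str))
        missing = [s for s in table.sample_ids if s not in df.index]
        if missing:
            raise TableError(f"metadata missing sample(s): {missing[:5]}")
        return SampleMetadata(
            df.loc[table.sample_ids].reset_index(drop=True),
            plant_composition=self.plant_composition,
        )


# ---------------------------------------------------------------------------
# I/O


def read_community_table(path: str | Path, format: str = "tsv") -> CommunityTable:
    """Read a community table from TSV (taxa as rows) or BIOM.

    TSV files are expected in the common ASV-table export layout: taxa as
    rows, samples as columns, a header row of sample IDs whose first token
    is the taxon-ID column name (``#OTU ID``, ``#ASV ID`` or similar). The
    returned table is normalised to samples x taxa.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom":
        import biom

        bt = biom.load_table(str(path))
        counts = np.asarray(bt.matrix_data.todense()).T  # biom is taxa x samples
        return CommunityTable(
            np.rint(counts).astype(np.int64),
            [str(s) for s in bt.ids("sample")],
            [str(o) for o in bt.ids("observation")],
        )
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")

    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None)
    if df.shape[0] == 0:
        raise TableError(f"{path}: no taxa (empty table body)")
    if df.shape[1] == 0:
        raise TableError(f"{path}: no samples (header has no sample IDs)")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise TableError(f"{path}: non-numeric count in column {col!r}, row {bad[0]!r}")
        if np.any(vals != np.floor(vals)):
            bad = df.index[vals != np.floor(vals)][0]
            raise TableError(f"{path}: non-integer count in column {col!r}, row {bad!r}")
        df[col] = vals.astype(np.int64)
    return CommunityTable(df.to_numpy().T, [str(c) for c in df.columns], [str(i) for i in df.index])


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    """Write a TSV with taxa as rows (the orientation `read_community_table` expects)."""
    df = pd.DataFrame(table.counts.T, index=table.taxon_ids, columns=table.sample_ids)
    df.index.name = "#ASV ID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filters


def filter_low_count_taxa(table: CommunityTable, min_reads: int = 8) -> CommunityTable:
    """Discard taxa whose total read count across all samples is below ``min_reads``.

    The default of 8 reads is the conventional cutoff for removing ASVs so
    scarce that their detection is essentially random. Totals equal to
    ``min_reads`` are retained (the rule is "fewer than", strictly).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.counts.sum(axis=0) >= min_reads
    out = CommunityTable(
        table.counts[:, keep],
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
    )
    if out.n_taxa == 0:
        out.warning = "all taxa removed by the low-count filter"
    return out


def rarefy(table: CommunityTable, depth: int = 9080, seed: int | None = None) -> CommunityTable:
    """Subsample every sample without replacement to a common read depth.

    Each sample is an exact multivariate-hypergeometric draw of ``depth``
    reads from its observed counts, so rarefied counts never exceed the
    originals and every row sum equals ``depth`` exactly. Deterministic
    given ``seed``.
    """
    depths = table.depth
    shallow = [s for s, d in zip(table.sample_ids, depths) if d < depth]
    if shallow:
        raise TableError(
            f"sample(s) shallower than rarefaction depth {depth}: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CommunityTable(out, list(table.sample_ids), list(table.taxon_ids))


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-sample proportions (rows sum to 1)."""
    depths = table.depth
    zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
    if zero:
        raise TableError(f"zero-depth sample(s): {zero}")
    rel = table.counts / depths[:, None]
    return pd.DataFrame(rel, index=table.sample_ids, columns=table.taxon_ids)


# ---------------------------------------------------------------------------
# Covariate handling


def derive_aridity(MAP: float | np.ndarray, PET: float | np.ndarray) -> float | np.ndarray:
    """Aridity level = 1 - AI where the aridity index AI = MAP / PET.

    MAP is mean annual precipitation (mm) and PET annual potential
    evapotranspiration (mm); higher values mean drier sites.
    """
    PET = np.asarray(PET, dtype=float)
    if np.any(PET <= 0):
        raise ValueError("PET must be > 0")
    out = 1.0 - np.asarray(MAP, dtype=float) / PET
    return float(out) if out.ndim == 0 else out


@dataclass
class CollinearityResult:
    retained: list[str]
    dropped: list[str]
    log: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {"retained": self.retained, "dropped": self.dropped, "log": self.log},
            indent=2,
        )


def collinearity_prune(covariates: pd.DataFrame, threshold: float = 0.6,
                       keep: Sequence[str] = ()) -> CollinearityResult:
    """Greedily drop covariates until no pair has |Pearson r| above ``threshold``.

    At each step the worst-offending pair is found and the member with the
    higher mean absolute correlation to all remaining covariates is dropped
    (names in ``keep`` are never dropped). Every drop is recorded so the
    decision can be audited or overridden.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    if covariates.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = covariates.std(axis=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant covariate(s), correlation undefined: {constant}")

    cols = list(covariates.columns)
    log: list[dict] = []
    dropped: list[str] = []
    while True:
        corr = covariates[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.to_numpy().max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(corr.to_numpy().argmax(), corr.shape)
        a, b = cols[i], cols[j]
        candidates = [c for c in (a, b) if c not in keep]
        if not candidates:
            raise ValueError(f"pair ({a}, {b}) exceeds threshold but both are protected")
        if len(candidates) == 2:
            # drop the one more entangled with everything else
            mean_a = corr.loc[a].mean()
            mean_b = corr.loc[b].mean()
            victim = a if mean_a >= mean_b else b
        else:
            victim = candidates[0]
        log.append({"pair": [a, b], "r": float(worst), "dropped": victim})
        dropped.append(victim)
        cols.remove(victim)
    return CollinearityResult(retained=cols, dropped=dropped, log=log)
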