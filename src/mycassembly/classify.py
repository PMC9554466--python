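"""Abundant / rare taxon classification and occupancy.

Taxa are partitioned by relative-abundance thresholds at two levels:

* **local** (single sample): relative abundance > 1% -> abundant,
  < 0.01% -> rare, otherwise intermediate;
* **regional** (mean over all samples): mean relative abundance > 0.1% ->
  abundant, < 0.005% -> rare, otherwise intermediate.

All inequalities are strict; boundary values fall to *intermediate*. The
regional mean is the unweighted mean of per-sample relative abundances over
every sample, zeros included. Downstream assembly analyses operate on the
regional abundant and rare subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CommunityTable, relative_abundance

__all__ = [
    "LOCAL_ABUNDANT",
    "LOCAL_RARE",
    "REGIONAL_ABUNDANT",
    "REGIONAL_RARE",
    "TaxonClassification",
    "classify_local",
    "classify_regional",
    "occupancy",
]

# thresholds as proportions
LOCAL_ABUNDANT = 0.01      # > 1% in a single sample
LOCAL_RARE = 0.0001        # < 0.01% in a single sample
REGIONAL_ABUNDANT = 0.001  # mean > 0.1% across all samples
REGIONAL_RARE = 0.00005    # mean < 0.005% across all samples


@dataclass
class TaxonClassification:
    """Per-taxon regional labels plus the quantities they are based on."""

    frame: pd.DataFrame  # index taxon_id; mean_rel_abund, occupancy, regional_label

    def taxa(self, label: str) -> list[str]:
        """Taxon IDs carrying a given regional label."""
        return self.frame.index[self.frame["regional_label"] == label].tolist()

    @property
    def abundant(self) -> list[str]:
        return self.taxa("abundant")

    @property
    def rare(self) -> list[str]:
        return self.taxa("rare")

    @property
    def intermediate(self) -> list[str]:
        return self.taxa("intermediate")


def _label(values: np.ndarray, hi: float, lo: float) -> np.ndarray:
    out = np.full(values.shape, "intermediate", dtype=object)
    out[values > hi] = "abundant"
    out[values < lo] = "rare"
    return out


def classify_local(rel: pd.DataFrame,
                   abundant_threshold: float = LOCAL_ABUNDANT,
                   rare_threshold: float = LOCAL_RARE) -> pd.DataFrame:
    """Label each (sample, taxon) cell as abundant / rare / intermediate.

    Taxa absent from a sample (abundance exactly 0) have nothing to
    classify locally and are labelled ``absent``.
    """
    vals = rel.to_numpy(float)
    labels = _label(vals, abundant_threshold, rare_threshold)
    labels[vals == 0] = "absent"
    return pd.DataFrame(labels, index=rel.index, columns=rel.columns)


def classify_regional(rel: pd.DataFrame,
                      abundant_threshold: float = REGIONAL_ABUNDANT,
                      rare_threshold: float = REGIONAL_RARE) -> TaxonClassification:
    """Classify taxa by their mean relative abundance over all samples."""
    mean = rel.to_numpy(float).mean(axis=0)
    occ = (rel.to_numpy(float) > 0).mean(axis=0)
    frame = pd.DataFrame(
        {
            "mean_rel_abund": mean,
            "occupancy": occ,
            "regional_label": _label(mean, abundant_threshold, rare_threshold),
        },
        index=pd.Index(rel.columns, name="taxon_id"),
    )
    return TaxonClassification(frame)


def occupancy(table: CommunityTable) -> pd.Series:
    """Fraction of samples in which each taxon is present (count > 0)."""
    frac = (table.counts > 0).mean(axis=0)
    return pd.Series(frac, index=table.taxon_ids, name="occupancy")
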