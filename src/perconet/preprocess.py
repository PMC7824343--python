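"""OTU-table filtering and cumulative sum scaling (CSS) normalization.

CSS corrects for library-size differences by dividing each sample's counts by
the cumulative sum of its counts up to a chosen quantile, rather than by the
total library size, so that a handful of dominant taxa do not drive the
scaling.  For sample ``j`` with percentile ``p``:

    q_j = p-th quantile of the *positive* counts of sample j
          (linear interpolation between order statistics)
    s_j = sum of counts[i, j] over all i with counts[i, j] <= q_j
    values[i, j] = counts[i, j] / s_j * N

Zeros are excluded from the quantile (sparse tables would otherwise give
``q_j = 0`` and break ``s_j > 0``) but ties equal to ``q_j`` are *included*
in the cumulative sum.  The percentile is fixed and configurable
(default 0.5, a median-quantile scaling) rather than chosen adaptively
per dataset, so results are deterministic and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

__all__ = ["NormalizedTable", "remove_singletons", "prevalence_filter", "css_normalize"]

logger = logging.getLogger(__name__)


@dataclass
class NormalizedTable:
    """CSS-normalized abundances with the scaling that produced them.

    ``values[i, j] = counts[i, j] / scaling_factors[j] * scale_constant``.
    Taxonomy and sample metadata are carried through unchanged.
    """

    values: pd.DataFrame
    scaling_factors: pd.Series
    percentile: float
    scale_constant: float
    taxonomy: pd.Series
    samples: pd.DataFrame

    @property
    def otu_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples is exactly 1.

    Such unique singletons are overwhelmingly sequencing artefacts and carry
    no co-occurrence information.  Removal is idempotent; removed ids are
    logged.
    """
    totals = table.counts.sum(axis=1)
    keep = totals != 1
    if not keep.any():
        raise ValueError("all OTUs removed: every OTU is a singleton")
    dropped = table.counts.index[~keep]
    if len(dropped):
        logger.info("remove_singletons: dropped %d OTU(s): %s",
                    len(dropped), ", ".join(map(str, dropped[:10])))
    return table.subset_otus(table.counts.index[keep])


def prevalence_filter(table: OtuTable, min_samples: int = 3) -> OtuTable:
    """Keep OTUs observed (count > 0) in at least ``min_samples`` samples.

    Rank correlation over a vector that is nonzero in a single sample is
    meaningless, so a prevalence floor is applied before building the
    co-occurrence matrix.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples "
            f"({table.n_samples})"
        )
    prevalence = (table.counts > 0).sum(axis=1)
    keep = prevalence >= min_samples
    if not keep.any():
        raise ValueError("all OTUs removed by prevalence filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence_filter(min_samples=%d): dropped %d OTU(s)",
                    min_samples, dropped)
    return table.subset_otus(table.counts.index[keep])


def css_normalize(table: OtuTable, percentile: float = 0.5,
                  scale_constant: float = 1000.0) -> NormalizedTable:
    """Cumulative-sum-scaling normalization of an OTU count table."""
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    if scale_constant <= 0:
        raise ValueError("scale_constant must be positive")

    counts = table.counts
    factors = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts; cannot CSS-normalize")
        q = np.quantile(positive, percentile, method="linear")
        s = col[col <= q].sum()
        factors[sample] = float(s)

    scaling = pd.Series(factors, name="css_scaling_factor").reindex(counts.columns)
    values = counts.div(scaling, axis=1) * scale_constant
    return NormalizedTable(
        values=values,
        scaling_factors=scaling,
        percentile=percentile,
        scale_constant=scale_constant,
        taxonomy=table.taxonomy,
        samples=table.samples,
    )
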