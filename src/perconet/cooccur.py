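"""Spearman co-occurrence matrices and positive-correlation networks.

Each OTU is a variable observed across samples; the co-occurrence matrix is
the Spearman rank correlation (Pearson correlation of mid-ranks, ties
averaged) between every pair of OTUs.  The network keeps only positive
correlations: nodes are OTUs annotated with their taxonomy, edges carry the
rho value as ``weight``.  Negative correlations are discarded at network
construction but the full signed matrix is retained for audit.

OTUs with zero variance across samples cannot be ranked informatively; their
correlations are set to 0 (not NaN) and a warning is emitted, which keeps
every downstream graph operation total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable
from .preprocess import NormalizedTable

__all__ = ["CorrelationMatrix", "spearman_matrix", "build_network",
           "permutation_pvalues"]


@dataclass
class CorrelationMatrix:
    """A symmetric OTU x OTU Spearman matrix with unit diagonal."""

    rho: pd.DataFrame
    n_samples: int

    def to_tsv(self, path) -> None:
        """Persist the full signed matrix (for audit) as TSV."""
        self.rho.to_csv(path, sep="\t", float_format="%.6f")


def spearman_matrix(values: OtuTable | NormalizedTable | pd.DataFrame) -> CorrelationMatrix:
    """Spearman rank correlation between all OTU pairs across samples.

    Accepts a raw :class:`OtuTable`, a CSS-:class:`NormalizedTable`, or a bare
    OTU x sample DataFrame.  Requires at least 3 samples.
    """
    if isinstance(values, OtuTable):
        matrix = values.counts
    elif isinstance(values, NormalizedTable):
        matrix = values.values
    else:
        matrix = values
    n_samples = matrix.shape[1]
    if n_samples < 3:
        raise ValueError("need >= 3 samples for a meaningful Spearman matrix")
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 OTUs")

    data = matrix.to_numpy(dtype=float)
    constant = data.std(axis=1) == 0
    # Pearson correlation of mid-ranks (ties averaged): the Spearman
    # convention that stays defined for heavily tied sparse counts.
    ranks = stats.rankdata(data, axis=1, method="average")
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} OTU(s) have zero variance across samples; "
            "their correlations are set to 0",
            stacklevel=2,
        )
    rho = np.nan_to_num(rho, nan=0.0)
    # enforce exact symmetry and unit diagonal
    rho = np.triu(rho, 1)
    rho = rho + rho.T
    np.fill_diagonal(rho, 1.0)
    frame = pd.DataFrame(rho, index=matrix.index, columns=matrix.index)
    return CorrelationMatrix(rho=frame, n_samples=n_samples)


def permutation_pvalues(values: OtuTable | NormalizedTable | pd.DataFrame,
                        n_perm: int = 500, seed: int = 0) -> pd.DataFrame:
    """Sample-permutation p-values for Spearman co-occurrences, BH-adjusted.

    Optional formal null for users who want more than a weight threshold:
    each permutation shuffles the sample order of every OTU independently,
    destroying co-variation while preserving marginal count distributions.
    The two-sided p-value of each pair is the fraction of permutations with
    |rho_perm| >= |rho_obs|, then Benjamini-Hochberg adjusted across the
    upper triangle.
    """
    if isinstance(values, OtuTable):
        matrix = values.counts
    elif isinstance(values, NormalizedTable):
        matrix = values.values
    else:
        matrix = values
    rng = np.random.default_rng(seed)
    observed = np.abs(spearman_matrix(matrix).rho.to_numpy())
    n_otus, n_samples = matrix.shape
    data = matrix.to_numpy(dtype=float)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        shuffled = rng.permuted(data, axis=1)
        ranks = stats.rankdata(shuffled, axis=1, method="average")
        with np.errstate(invalid="ignore"):
            perm_rho = np.nan_to_num(np.corrcoef(ranks), nan=0.0)
        exceed += np.abs(perm_rho) >= observed
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    iu = np.triu_indices(n_otus, k=1)
    flat = pvals[iu]
    # Benjamini-Hochberg over the unique pairs
    order = np.argsort(flat)
    ranked = flat[order] * len(flat) / (np.arange(len(flat)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.ones_like(pvals)
    out[iu] = adjusted[np.argsort(order)]
    out = np.minimum(out, 1.0)
    out[(iu[1], iu[0])] = out[iu]
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


def build_network(corr: CorrelationMatrix, taxonomy: pd.Series | None = None,
                  min_weight: float = 0.0) -> nx.Graph:
    """The positive-correlation network of a Spearman matrix.

    An edge (i, k) is drawn iff ``rho[i, k] > 0`` and ``rho[i, k] >=
    min_weight``; isolated OTUs are retained as degree-0 nodes.  The applied
    threshold is recorded on the graph (``threshold_applied``).
    """
    if not 0.0 <= min_weight < 1.0:
        raise ValueError("min_weight must lie in [0, 1)")
    rho = corr.rho
    g = nx.Graph(threshold_applied=min_weight)
    for otu in rho.index:
        lineage = "" if taxonomy is None else str(taxonomy.get(otu, ""))
        g.add_node(otu, taxonomy=lineage)
    values = rho.to_numpy()
    ids = list(rho.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        w = values[i, j]
        if w > 0 and w >= min_weight:
            g.add_edge(ids[i], ids[j], weight=float(w))
    return g
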