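"""Alpha diversity (Shannon, Simpson) and Bray-Curtis beta diversity.

Conventions: Shannon entropy H' uses the natural log; Simpson diversity is
reported as 1 - D = 1 - sum(p_i^2), the probability that two randomly drawn
reads belong to different taxa.  Both are computed on raw counts by default:
per-sample rescaling (CSS or relative abundance) leaves the proportions p_i,
and hence both indices, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform

from .io import OtuTable
from .preprocess import NormalizedTable

__all__ = [
    "shannon",
    "simpson",
    "bray_curtis",
    "DiversityReport",
    "diversity_report",
    "dissimilarity_network",
]


def _proportions(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    return x / total


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H' = -sum(p_i log p_i), zero entries skipped.

    Natural log by default; pass ``base`` (e.g. 2) for another convention.
    """
    p = _proportions(abundances)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base is not None else h


def simpson(abundances, form: str = "1-D") -> float:
    """Simpson diversity, by default the complement 1 - D = 1 - sum(p_i^2).

    ``form`` selects the reported convention: "1-D" (probability two random
    reads differ), "D" (dominance sum(p_i^2)), or "1/D" (inverse Simpson).
    """
    p = _proportions(abundances)
    d = float((p ** 2).sum())
    if form == "1-D":
        return 1.0 - d
    if form == "D":
        return d
    if form == "1/D":
        return 1.0 / d
    raise ValueError("form must be one of '1-D', 'D', '1/D'")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("both vectors are all-zero; dissimilarity undefined")
    return float(_braycurtis(x, y))


@dataclass
class DiversityReport:
    """Per-sample alpha diversity plus the pairwise Bray-Curtis matrix."""

    shannon: pd.Series
    simpson: pd.Series
    braycurtis: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shannon": self.shannon, "simpson": self.simpson})


def diversity_report(table: OtuTable | NormalizedTable) -> DiversityReport:
    """Shannon/Simpson per sample and the sample x sample Bray-Curtis matrix."""
    matrix = table.counts if isinstance(table, OtuTable) else table.values
    cols = matrix.columns
    sh = pd.Series({s: shannon(matrix[s]) for s in cols}, name="shannon")
    si = pd.Series({s: simpson(matrix[s]) for s in cols}, name="simpson")
    bc = squareform(pdist(matrix.T.to_numpy(dtype=float), metric="braycurtis"))
    bc_df = pd.DataFrame(bc, index=cols, columns=cols)
    return DiversityReport(shannon=sh, simpson=si, braycurtis=bc_df)


def dissimilarity_network(table: OtuTable | NormalizedTable,
                          max_bc: float) -> nx.Graph:
    """A sample-similarity network: edge (a, b) iff BC(a, b) <= ``max_bc``.

    Edge weight is the similarity 1 - BC; each node carries its sample
    ``group`` as an attribute.
    """
    if not 0.0 <= max_bc <= 1.0:
        raise ValueError("max_bc must lie in [0, 1]")
    report = diversity_report(table)
    samples = table.samples
    g = nx.Graph()
    for s in report.braycurtis.index:
        group = samples.loc[s, "group"] if "group" in samples.columns else ""
        g.add_node(s, group=str(group))
    cols = list(report.braycurtis.index)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            bc = float(report.braycurtis.loc[a, b])
            if bc <= max_bc:
                g.add_edge(a, b, weight=1.0 - bc)
    return g
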