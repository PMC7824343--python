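"""The co-occurrence analysis model: one object from OTU table to report.

``CooccurrenceAnalysis`` bundles the whole inference chain behind a
model/results interface: construct it from an :class:`~perconet.io.OtuTable`
(or from TSV files), call :meth:`~CooccurrenceAnalysis.fit`, and read the
resulting :class:`CooccurrenceResults` — the Spearman matrix, the
positive-correlation network, the percolation threshold and trajectory, the
module partition with its modularity Q, the per-module composition, and (if a
target lineage is given) the focus report.

The fitted chain is: singleton removal -> prevalence filter -> CSS
normalization -> Spearman matrix -> positive network -> percolation
threshold -> thresholded network -> Louvain modules -> summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from . import communities, cooccur, focus as focus_mod, percolation, preprocess
from .io import OtuTable, read_otu_table

__all__ = ["CooccurrenceAnalysis", "CooccurrenceResults"]


@dataclass
class CooccurrenceResults:
    """Everything the fitted co-occurrence chain produced."""

    table: OtuTable
    normalized: preprocess.NormalizedTable | None
    corr: cooccur.CorrelationMatrix
    network: nx.Graph
    percolation: percolation.PercolationResult
    network_at_threshold: nx.Graph
    partition: communities.ModulePartition
    module_summary: communities.ModuleSummary
    focus: focus_mod.FocusReport | None = None
    threshold: float = 0.0
    params: dict = field(default_factory=dict)

    @property
    def t_star(self) -> float:
        return self.percolation.t_star

    @property
    def Q(self) -> float:
        return self.partition.Q

    def summary(self) -> str:
        lines = [
            "Co-occurrence network analysis",
            "=" * 46,
            f"OTUs analysed            {self.table.n_otus:>8d}",
            f"Samples                  {self.table.n_samples:>8d}",
            f"Positive edges           {self.network.number_of_edges():>8d}",
            f"Percolation threshold t* {self.t_star:>8.3f}"
            + ("  (largest component)" if self.percolation.fragmented else ""),
            f"Threshold applied        {self.threshold:>8.3f}",
            f"Edges at threshold       {self.network_at_threshold.number_of_edges():>8d}",
            f"Modules                  {self.partition.n_modules:>8d}",
            f"Modularity Q             {self.Q:>8.3f}",
        ]
        if self.focus is not None:
            counts = self.focus.partner_counts
            lines.append(
                f"Focus '{self.focus.target_lineage}' "
                f"(w >= {self.focus.w_min}): "
                f"{len(counts)} OTU(s), partners "
                f"{sorted(counts.values(), reverse=True)}"
            )
        return "\n".join(lines)

    def plot_percolation(self, ax=None):
        """Giant-component size S(t) against the weight cutoff t."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.percolation.trajectory
        ax.step(traj["threshold"], traj["S"], where="post")
        ax.axvline(self.t_star, linestyle="--", color="crimson",
                   label=f"t* = {self.t_star:.3f}")
        ax.set_xlabel("edge-weight cutoff t")
        ax.set_ylabel("giant component size S(t)")
        ax.legend()
        return ax


class CooccurrenceAnalysis:
    """Model object for percolation-threshold co-occurrence analysis.

    Parameters
    ----------
    table : OtuTable
        Counts, taxonomy and sample metadata.
    correlate_on : {"css", "raw", "relative"}
        Whether Spearman correlations are computed on CSS-normalized values
        (default), raw counts, or per-sample relative abundances.
        (Spearman is rank-based, so this matters
        only when the per-sample scaling changes ranks across samples —
        which CSS does.)
    drop_singletons, min_samples :
        Filtering applied before correlation (singleton removal, prevalence
        floor).
    css_percentile, scale_constant :
        CSS parameters.
    min_weight : float
        Positive-correlation floor for the un-thresholded network.
    threshold : "auto" or float
        "auto" analyses the network at its percolation threshold t*; a float
        overrides it (the study style of dropping to 0.7 when focal OTUs
        detach).
    resolution, seed :
        Louvain resolution gamma and shuffle seed.
    target_lineage, w_min, rank :
        Focus-report settings; ``target_lineage=None`` skips the report.
    """

    def __init__(self, table: OtuTable, *, correlate_on: str = "css",
                 drop_singletons: bool = True, min_samples: int = 3,
                 css_percentile: float = 0.5, scale_constant: float = 1000.0,
                 min_weight: float = 0.0, threshold="auto",
                 resolution: float = 1.0, seed: int = 0,
                 target_lineage: str | None = None, w_min: float = 0.7,
                 rank: str = "order"):
        if correlate_on not in ("css", "raw", "relative"):
            raise ValueError("correlate_on must be 'css', 'raw' or 'relative'")
        if threshold != "auto" and not isinstance(threshold, (int, float)):
            raise ValueError("threshold must be 'auto' or a number")
        self.table = table
        self.params = dict(
            correlate_on=correlate_on, drop_singletons=drop_singletons,
            min_samples=min_samples, css_percentile=css_percentile,
            scale_constant=scale_constant, min_weight=min_weight,
            threshold=threshold, resolution=resolution, seed=seed,
            target_lineage=target_lineage, w_min=w_min, rank=rank,
        )

    @classmethod
    def from_files(cls, counts_path, taxonomy_path, metadata_path, **kwargs):
        return cls(read_otu_table(counts_path, taxonomy_path, metadata_path),
                   **kwargs)

    def fit(self) -> CooccurrenceResults:
        p = self.params
        table = self.table
        if p["drop_singletons"]:
            table = preprocess.remove_singletons(table)
        table = preprocess.prevalence_filter(table, p["min_samples"])

        normalized = None
        if p["correlate_on"] == "css":
            normalized = preprocess.css_normalize(
                table, percentile=p["css_percentile"],
                scale_constant=p["scale_constant"],
            )
            corr = cooccur.spearman_matrix(normalized)
        elif p["correlate_on"] == "relative":
            relative = table.counts.div(table.counts.sum(axis=0), axis=1)
            corr = cooccur.spearman_matrix(relative)
        else:
            corr = cooccur.spearman_matrix(table)

        network = cooccur.build_network(corr, table.taxonomy,
                                        min_weight=p["min_weight"])
        perc = percolation.percolation_threshold(network)
        threshold = perc.t_star if p["threshold"] == "auto" else float(p["threshold"])
        thresholded = percolation.apply_threshold(network, threshold)

        partition = communities.louvain_partition(
            thresholded, resolution=p["resolution"], seed=p["seed"]
        )
        summary = communities.summarize_modules(
            partition, table.taxonomy, rank=p["rank"],
            target_lineage=p["target_lineage"],
        )
        focus_report = None
        if p["target_lineage"]:
            focus_report = focus_mod.focus_report(
                thresholded, partition, p["target_lineage"], w_min=p["w_min"]
            )
        return CooccurrenceResults(
            table=table, normalized=normalized, corr=corr, network=network,
            percolation=perc, network_at_threshold=thresholded,
            partition=partition, module_summary=summary, focus=focus_report,
            threshold=threshold, params=dict(p),
        )
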