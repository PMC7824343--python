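"""Percolation threshold of a weighted co-occurrence network.

The percolation threshold t* is the largest edge-weight cutoff at which the
network still forms a single connected giant cluster: raise the cutoff any
further and the system fragments.  For a weighted graph this is exactly the
*bottleneck* of a maximum spanning tree — the smallest edge weight on the
tree that connects every node with the strongest possible links — which is
how it is computed here.  A descending scan over the unique edge weights
provides both the giant-component trajectory S(t) and an independent check
of the MST value.

If the input network is already disconnected, the threshold is computed on
its largest connected component and the result carries a fragmentation flag.
Thresholds iterate over unique weights only, so equal-weight edges always
enter or leave together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["PercolationResult", "percolation_threshold", "apply_threshold"]


@dataclass
class PercolationResult:
    """Percolation threshold plus the giant-component trajectory.

    ``trajectory`` has one row per unique edge weight ``t`` (descending) with
    the giant component size ``S`` and retained edge count ``E`` of the
    subgraph with edges of weight >= t.
    """

    t_star: float
    trajectory: pd.DataFrame
    component_at_t_star: set = field(default_factory=set)
    fragmented: bool = False

    def trajectory_tsv(self, path) -> None:
        self.trajectory.to_csv(path, sep="\t", index=False)


def percolation_threshold(network: nx.Graph) -> PercolationResult:
    """Compute t* and the S(t)/E(t) trajectory of a weighted network.

    The analysed node set is the set of nodes with degree >= 1; fully
    isolated nodes can never percolate and are ignored.
    """
    if network.number_of_edges() == 0:
        raise ValueError("no edges; percolation undefined")

    analysed = [n for n in network.nodes if network.degree(n) >= 1]
    sub = network.subgraph(analysed)
    fragmented = not nx.is_connected(sub)
    if fragmented:
        warnings.warn(
            "network is disconnected; percolation threshold computed on the "
            "largest connected component",
            stacklevel=2,
        )
        giant = max(nx.connected_components(sub), key=len)
        sub = sub.subgraph(giant)

    mst = nx.maximum_spanning_tree(sub, weight="weight")
    t_star = min(d["weight"] for _, _, d in mst.edges(data=True))

    # descending scan with incremental union-find over the analysed nodes
    edges = sorted(network.subgraph(analysed).edges(data="weight"),
                   key=lambda e: -e[2])
    uf = nx.utils.UnionFind(analysed)
    comp_size = {uf[n]: 1 for n in analysed}
    rows = []
    n_edges = 0
    giant_size = 1
    i = 0
    uniques = sorted({w for _, _, w in edges}, reverse=True)
    for t in uniques:
        while i < len(edges) and edges[i][2] >= t:
            u, v, _ = edges[i]
            ru, rv = uf[u], uf[v]
            if ru != rv:
                su, sv = comp_size.pop(ru), comp_size.pop(rv)
                uf.union(u, v)
                comp_size[uf[u]] = su + sv
                giant_size = max(giant_size, su + sv)
            n_edges += 1
            i += 1
        rows.append((t, giant_size, n_edges))
    trajectory = pd.DataFrame(rows, columns=["threshold", "S", "E"])

    component = set(sub.nodes)
    return PercolationResult(
        t_star=float(t_star),
        trajectory=trajectory,
        component_at_t_star=component,
        fragmented=fragmented,
    )


def apply_threshold(network: nx.Graph, t: float) -> nx.Graph:
    """Retain edges of weight >= ``t``; all nodes are kept.

    Records ``threshold_applied = t`` on the returned graph.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    g = network.copy()
    drop = [(u, v) for u, v, w in g.edges(data="weight") if w < t]
    g.remove_edges_from(drop)
    g.graph["threshold_applied"] = float(t)
    return g
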