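"""Focus-taxon reports: the strong co-occurrence partners of a target lineage.

For every OTU whose lineage matches the target (case-insensitive substring of
the full lineage string), list its network neighbours with edge weight at or
above ``w_min`` (default 0.7, a conventional floor for "strong, non-random"
rank correlation in sparse amplicon data), annotated with the partner's
lineage and whether it shares the target's module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .communities import ModulePartition

__all__ = ["FocusReport", "focus_report"]


@dataclass
class FocusReport:
    """Partners of each target OTU, sorted by descending weight.

    ``targets`` maps target otu_id -> list of dicts with keys ``partner``,
    ``lineage``, ``weight``, ``same_module``.
    """

    targets: dict
    target_lineage: str
    w_min: float
    threshold_applied: float | None = None

    @property
    def partner_counts(self) -> dict:
        return {otu: len(partners) for otu, partners in self.targets.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for otu, partners in self.targets.items():
            for p in partners:
                rows.append({"target": otu, **p})
        return pd.DataFrame(
            rows, columns=["target", "partner", "lineage", "weight", "same_module"]
        )

    def to_json(self, path) -> None:
        payload = {
            "target_lineage": self.target_lineage,
            "w_min": self.w_min,
            "threshold_applied": self.threshold_applied,
            "targets": self.targets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def focus_report(network: nx.Graph, partition: ModulePartition | None,
                 target_lineage: str, w_min: float = 0.7) -> FocusReport:
    """Strong co-occurrence partners of every target-lineage OTU.

    ``partition`` should have been computed on the same (thresholded) network;
    pass None to omit module co-membership annotation.
    """
    if w_min < 0:
        raise ValueError("w_min must be >= 0")
    needle = target_lineage.lower()
    assignment = partition.assignment if partition is not None else {}

    target_otus = [
        n for n, data in network.nodes(data=True)
        if needle in str(data.get("taxonomy", "")).lower()
    ]
    if not target_otus:
        warnings.warn(
            f"target lineage {target_lineage!r} matches no OTU in the network",
            stacklevel=2,
        )

    targets = {}
    for otu in target_otus:
        partners = []
        for nbr in network.neighbors(otu):
            w = float(network.edges[otu, nbr]["weight"])
            if w >= w_min:
                partners.append({
                    "partner": nbr,
                    "lineage": str(network.nodes[nbr].get("taxonomy", "")),
                    "weight": w,
                    "same_module": (
                        assignment.get(otu) == assignment.get(nbr)
                        if assignment else None
                    ),
                })
        partners.sort(key=lambda p: -p["weight"])
        targets[otu] = partners

    return FocusReport(
        targets=targets,
        target_lineage=target_lineage,
        w_min=w_min,
        threshold_applied=network.graph.get("threshold_applied"),
    )
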