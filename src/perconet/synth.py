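"""Synthetic OTU tables with planted co-occurrence structure, and synthetic qPCR runs.

The count generator emulates the features of sparse amplicon tables that the
analysis chain actually relies on: overdispersed counts (negative binomial),
uneven library sizes, rare singleton OTUs, and *planted blocks* of positively
co-varying taxa.  Each block k shares a latent factor f_k(s) ~ N(0,
latent_sd) per sample; a member OTU i has log mean a_i + b_i * f_k(s) with
loading b_i drawn from ``loading_range``, so block members rise and fall
together across samples and are rank-correlated by construction.  Background
OTUs have a constant log mean (their counts vary only through sampling
noise), and one designated block carries a target lineage
(*Methanomassiliicoccales*-style) so focus reports can be validated against
ground truth.

Also provides planted two-block benchmark graphs and random weighted graphs
used as oracles for the percolation and modularity code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import OtuTable, QpcrRun

__all__ = [
    "BlockSpec",
    "SyntheticSpec",
    "generate_table",
    "generate_qpcr",
    "planted_partition_graph",
    "random_weighted_graph",
    "block_recovery_ari",
]

TARGET_LINEAGE = (
    "Archaea;Thermoplasmatota;Thermoplasmata;Methanomassiliicoccales;"
    "Methanomassiliicoccaceae;Methanomassiliicoccus"
)

_PARTNER_LINEAGES = (
    "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Dysgonomonadaceae;Dysgonomonas",
    "Bacteria;Synergistota;Synergistia;Synergistales;Synergistaceae;Synergistes",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminiclostridium",
)

_BACKGROUND_LINEAGES = (
    "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfovibrionales;Desulfovibrionaceae;Desulfovibrio",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;Anaerolinea",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium",
    "Bacteria;Firmicutes;Clostridia;Peptostreptococcales-Tissierellales;Anaerovoracaceae;Anaerovorax",
    "Bacteria;Acidobacteriota;Aminicenantia;Aminicenantales;Unclassified;Unclassified",
    "Bacteria;Unclassified;Unclassified;Unclassified;Unclassified;Unclassified",
)


@dataclass
class BlockSpec:
    """One planted block of positively co-varying OTUs."""

    size: int = 10
    latent_sd: float = 1.5
    loading_range: tuple = (0.8, 1.2)
    lineage_label: str = _BACKGROUND_LINEAGES[0]


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic OTU table.

    Defaults describe the standard study-like condition: 40 samples, 300
    OTUs, four planted blocks of 10 OTUs each (the first carrying the target
    lineage), latent sd 1.5, loadings 0.8-1.2, uneven libraries of
    5000-50000 reads, negative-binomial dispersion k = 5, 10 singleton OTUs.
    """

    n_samples: int = 40
    n_otus: int = 300
    library_size_range: tuple = (5000, 50000)
    blocks: list = field(default_factory=lambda: [
        BlockSpec(lineage_label=TARGET_LINEAGE),
        BlockSpec(lineage_label=_PARTNER_LINEAGES[0]),
        BlockSpec(lineage_label=_PARTNER_LINEAGES[1]),
        BlockSpec(lineage_label=_PARTNER_LINEAGES[2]),
    ])
    target_block_index: int = 0
    background_dispersion: float = 5.0
    base_log_sd: float = 1.0
    n_singletons: int = 10
    seed: int = 0

    def validate(self) -> None:
        planted = sum(b.size for b in self.blocks)
        if planted + self.n_singletons >= self.n_otus:
            raise ValueError(
                f"infeasible sizes: {planted} block OTUs + {self.n_singletons} "
                f"singletons leave no background among {self.n_otus} OTUs"
            )
        if self.blocks and not 0 <= self.target_block_index < len(self.blocks):
            raise ValueError("target_block_index out of range")
        if self.library_size_range[0] < 1 or \
                self.library_size_range[0] > self.library_size_range[1]:
            raise ValueError("invalid library_size_range")
        if self.background_dispersion <= 0:
            raise ValueError("background_dispersion must be positive")


def generate_table(spec: SyntheticSpec | None = None):
    """Generate a synthetic OtuTable plus its planted-block ground truth.

    Returns ``(table, ground_truth)`` where ``ground_truth`` maps otu_id to
    its block index, or ``None`` for background and singleton OTUs.  The seed
    fully determines the output.
    """
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_blocks = len(spec.blocks)
    n_planted = sum(b.size for b in spec.blocks)
    n_background = spec.n_otus - n_planted - spec.n_singletons

    # expected relative abundances on the log scale
    rows, lineages, truth = [], [], []
    for b, block in enumerate(spec.blocks):
        f = rng.normal(0.0, block.latent_sd, spec.n_samples)
        a = rng.normal(0.0, spec.base_log_sd, block.size)
        load = rng.uniform(*block.loading_range, block.size)
        rows.append(np.exp(a[:, None] + load[:, None] * f[None, :]))
        lineages += [block.lineage_label] * block.size
        truth += [b] * block.size
    a_bg = rng.normal(0.0, spec.base_log_sd, n_background)
    rows.append(np.exp(a_bg)[:, None] * np.ones((1, spec.n_samples)))
    lineages += [
        _BACKGROUND_LINEAGES[i % len(_BACKGROUND_LINEAGES)]
        for i in range(n_background)
    ]
    truth += [None] * n_background

    mu = np.vstack(rows)
    lo, hi = spec.library_size_range
    libraries = rng.integers(lo, hi + 1, spec.n_samples)
    mu = mu / mu.sum(axis=0, keepdims=True) * libraries[None, :]

    k = spec.background_dispersion
    counts = rng.negative_binomial(k, k / (k + mu)).astype(int)

    # singleton OTUs: exactly one read in the whole table
    singleton_rows = np.zeros((spec.n_singletons, spec.n_samples), dtype=int)
    for i in range(spec.n_singletons):
        singleton_rows[i, rng.integers(spec.n_samples)] = 1
    counts = np.vstack([counts, singleton_rows])
    lineages += [_BACKGROUND_LINEAGES[-1]] * spec.n_singletons
    truth += [None] * spec.n_singletons

    otu_ids = [f"OTU{i + 1:04d}" for i in range(spec.n_otus)]
    sample_ids = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    groups = ["PENF", "DOUR", "MOUG"]
    samples = pd.DataFrame(
        {
            "group": [groups[j % len(groups)] for j in range(spec.n_samples)],
            "timepoint": list(range(spec.n_samples)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = OtuTable(
        counts=pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                            columns=sample_ids),
        taxonomy=pd.Series(lineages, index=otu_ids, name="lineage"),
        samples=samples,
    )
    ground_truth = dict(zip(otu_ids, truth))
    return table, ground_truth


def generate_qpcr(copies_truth, ct_sd: float = 0.1, replicates: int = 3,
                  seed: int = 0, slope: float = -3.3219,
                  intercept: float = 38.0,
                  ladder_log10=tuple(range(-1, 9)),
                  units: str = "mL") -> QpcrRun:
    """Simulate a qPCR run: a standard dilution ladder plus unknowns.

    ``copies_truth`` maps (sample_id, timepoint) -> true gene copies per
    unit.  Ct values follow the line ``intercept + slope * log10(copies)``
    with Gaussian noise of sd ``ct_sd``.  The default ladder spans 10^-1 to
    10^8 copies (10 points).
    """
    rng = np.random.default_rng(seed)
    std_rows = []
    for log10_copies in ladder_log10:
        for rep in range(replicates):
            ct = intercept + slope * log10_copies + rng.normal(0.0, ct_sd)
            std_rows.append({
                "known_log10_copies": float(log10_copies),
                "ct": float(ct),
                "replicate": rep,
            })
    unk_rows = []
    for (sample_id, timepoint), copies in copies_truth.items():
        for rep in range(replicates):
            ct = intercept + slope * np.log10(copies) + rng.normal(0.0, ct_sd)
            unk_rows.append({
                "sample_id": sample_id,
                "timepoint": timepoint,
                "ct": float(ct),
                "replicate": rep,
                "dilution_factor": 1.0,
                "mass_or_volume": 1.0,
                "units": units,
            })
    return QpcrRun(
        standards=pd.DataFrame(std_rows),
        unknowns=pd.DataFrame(unk_rows),
    )


def planted_partition_graph(block_sizes=(30, 30), p_in: float = 0.9,
                            w_in: float = 0.9, p_out: float = 0.05,
                            w_out: float = 0.75, seed: int = 0):
    """A two-(or more-)block planted-partition benchmark graph.

    Within-block edges appear with probability ``p_in`` and weight ``w_in``;
    between-block edges with probability ``p_out`` and weight ``w_out``.
    Returns ``(graph, truth)`` with truth mapping node -> block index.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    truth = {}
    node = 0
    blocks = []
    for b, size in enumerate(block_sizes):
        members = list(range(node, node + size))
        blocks.append(members)
        for n in members:
            g.add_node(n)
            truth[n] = b
        node += size
    nodes = list(g.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            same = truth[u] == truth[v]
            p, w = (p_in, w_in) if same else (p_out, w_out)
            if rng.random() < p:
                g.add_edge(u, v, weight=w)
    return g, truth


def random_weighted_graph(n: int, p: float = 0.3, seed: int = 0) -> nx.Graph:
    """A G(n, p) graph with distinct edge weights drawn uniformly in (0, 1)."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
    m = g.number_of_edges()
    weights = rng.permutation(m) + rng.random(m)  # distinct by construction
    weights = weights / (m + 1.0)
    for (u, v), w in zip(g.edges, weights):
        g.edges[u, v]["weight"] = float(w)
    return g


def block_recovery_ari(assignment: dict, ground_truth: dict) -> float:
    """Adjusted Rand index between detected modules and planted blocks.

    Restricted to planted block members: background OTUs have no planted
    community and legitimately scatter across modules.
    """
    members = [o for o, b in ground_truth.items() if b is not None
               and o in assignment]
    if not members:
        raise ValueError("no planted block members present in the assignment")
    truth = [ground_truth[o] for o in members]
    found = [assignment[o] for o in members]
    return float(adjusted_rand_score(truth, found))
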