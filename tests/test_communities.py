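import networkx as nx
import numpy as np
import pandas as pd
import pytest

from perconet import (
    louvain_partition,
    modularity_score,
    summarize_modules,
)
from perconet.synth import planted_partition_graph, random_weighted_graph


def modularity_double_sum(g: nx.Graph, assignment: dict, gamma: float = 1.0) -> float:
    """Independent O(n^2) evaluation of Q over the full node-pair double sum."""
    nodes = list(g.nodes)
    m = sum(w for _, _, w in g.edges(data="weight", default=1.0))
    if m == 0:
        return 0.0
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    k = a.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if assignment[u] == assignment[v]:
                q += a[i, j] - gamma * k[i] * k[j] / (2 * m)
    return q / (2 * m)


def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)],
                     weight=1.0)
    return g


class TestModularityScore:
    def test_disjoint_triangles_q_half(self):
        g = two_triangles()
        assignment = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity_score(g, assignment) == pytest.approx(0.5, abs=1e-15)

    def test_single_community_q_zero(self):
        g = nx.cycle_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        assignment = {n: 0 for n in g.nodes}
        assert modularity_score(g, assignment) == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_sum_oracle_on_random_graphs(self, rng):
        for seed in range(10):
            g = random_weighted_graph(18, p=0.3, seed=seed)
            assignment = {n: int(rng.integers(4)) for n in g.nodes}
            expected = modularity_double_sum(g, assignment)
            assert modularity_score(g, assignment) == pytest.approx(
                expected, abs=1e-12
            )

    def test_agrees_with_networkx_reference(self):
        g = random_weighted_graph(20, p=0.3, seed=11)
        comms = [set(range(0, 10)), set(range(10, 20))]
        assignment = {n: (0 if n < 10 else 1) for n in g.nodes}
        expected = nx.community.modularity(g, comms, weight="weight")
        assert modularity_score(g, assignment) == pytest.approx(expected, abs=1e-12)


class TestLouvainPartition:
    def test_two_triangles_recovered(self):
        part = louvain_partition(two_triangles(), seed=0)
        assert part.Q == pytest.approx(0.5, abs=1e-12)
        assert len({part.assignment[n] for n in (0, 1, 2)}) == 1
        assert len({part.assignment[n] for n in (3, 4, 5)}) == 1
        assert part.assignment[0] != part.assignment[3]

    def test_reported_q_equals_direct_evaluation(self):
        for seed in range(5):
            g = random_weighted_graph(40, p=0.15, seed=seed)
            part = louvain_partition(g, seed=seed)
            assert part.Q == modularity_score(g, part.assignment)

    def test_q_at_least_singleton_partition(self):
        g = random_weighted_graph(30, p=0.2, seed=3)
        part = louvain_partition(g, seed=3)
        singletons = {n: i for i, n in enumerate(g.nodes)}
        assert part.Q >= modularity_score(g, singletons)

    def test_planted_two_blocks_recovered(self):
        for seed in range(5):
            g, truth = planted_partition_graph(seed=seed)
            part = louvain_partition(g, seed=seed)
            blocks = {}
            for node, block in truth.items():
                blocks.setdefault(block, set()).add(part.assignment[node])
            assert all(len(mods) == 1 for mods in blocks.values())
            assert blocks[0] != blocks[1]

    def test_deterministic_for_fixed_seed(self):
        g = random_weighted_graph(50, p=0.1, seed=2)
        a = louvain_partition(g, seed=42).assignment
        b = louvain_partition(g, seed=42).assignment
        assert a == b

    def test_isolated_nodes_become_singletons(self):
        g = two_triangles()
        g.add_node("lonely")
        part = louvain_partition(g, seed=0)
        assert part.assignment["lonely"] not in {
            part.assignment[n] for n in range(6)
        }

    def test_edgeless_network_all_singletons_with_warning(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.warns(UserWarning, match="edgeless"):
            part = louvain_partition(g)
        assert part.Q == 0.0
        assert len(set(part.assignment.values())) == 3

    def test_module_ids_ordered_by_size(self):
        g = two_triangles()
        g.add_edge(6, 7, weight=1.0)  # a smaller third community
        part = louvain_partition(g, seed=0)
        sizes = {}
        for mid in part.assignment.values():
            sizes[mid] = sizes.get(mid, 0) + 1
        ordered = [sizes[mid] for mid in sorted(sizes)]
        assert ordered == sorted(ordered, reverse=True)


class TestSummarizeModules:
    TAX = pd.Series({
        "t1": "Archaea;Thermoplasmatota;Thermoplasmata;Methanomassiliicoccales;F;G",
        "b1": "Bacteria;Firmicutes;Clostridia;Clostridiales;F;G",
        "b2": "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;F;G",
    })

    def _partition(self, assignment):
        from perconet import ModulePartition
        return ModulePartition(assignment=assignment, Q=0.0)

    def test_target_module_flagged_with_count(self):
        part = self._partition({"t1": 0, "b1": 0, "b2": 0})
        summary = summarize_modules(part, self.TAX, rank="order",
                                    target_lineage="Methanomassiliicoccales")
        info = summary.modules[0]
        assert info["contains_target"] and info["n_target"] == 1
        assert not info["singleton_target"]

    def test_single_target_module_marked_singleton_target(self):
        part = self._partition({"t1": 0, "b1": 1, "b2": 1})
        summary = summarize_modules(part, self.TAX, rank="order",
                                    target_lineage="methanomassiliicoccales")
        assert summary.modules[0]["singleton_target"]

    def test_histogram_totals_conserve_module_sizes(self, rng):
        nodes = [f"o{i}" for i in range(30)]
        tax = pd.Series({
            n: f"Bacteria;P;C;Order{rng.integers(4)};F;G" for n in nodes
        })
        part = self._partition({n: int(rng.integers(5)) for n in nodes})
        summary = summarize_modules(part, tax, rank="order")
        for info in summary.modules.values():
            assert sum(info["histogram"].values()) == info["size"]
        assert sum(i["size"] for i in summary.modules.values()) == 30

    def test_unknown_rank_rejected(self):
        part = self._partition({"t1": 0})
        with pytest.raises(ValueError, match="rank"):
            summarize_modules(part, self.TAX, rank="species")
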