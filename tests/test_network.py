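"""Co-occurrence null model, edge filtering, module detection, labelling."""

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest

from weedpool import (
    IncidenceMatrix,
    assign_main_habitat,
    assign_plot_habitats,
    build_incidence,
    cooccurrence_edges,
    detect_modules,
    filter_edges,
    pair_null_test,
)
from weedpool.network import CooccurrenceEdge


class TestBuildIncidence:
    def test_small_matrix(self):
        inc = build_incidence([("p1", "a"), ("p1", "b"), ("p2", "a")],
                              min_occupancy=1)
        assert inc.presence.sum() == 3
        assert inc.plots == ["p1", "p2"] and inc.species == ["a", "b"]

    def test_duplicates_collapse(self):
        inc = build_incidence([("p1", "a")] * 5, min_occupancy=1)
        assert inc.presence.sum() == 1

    def test_occupancy_matches_counting_oracle(self, rng):
        records = [(f"p{rng.integers(20)}", f"s{rng.integers(15)}")
                   for _ in range(200)]
        inc = build_incidence(records, min_occupancy=1)
        unique = set(records)
        for j, sp in enumerate(inc.species):
            assert inc.occupancy[j] == sum(1 for _, s in unique if s == sp)

    def test_min_occupancy_drops_rare_species(self):
        records = [("p1", "common"), ("p2", "common"), ("p3", "common"),
                   ("p1", "rare")]
        inc = build_incidence(records, min_occupancy=3)
        assert inc.species == ["common"]

    def test_malformed_record_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            build_incidence([("p1", "a"), ("p2", "")], min_occupancy=1)


def enumerate_tail(shared, occ_i, occ_j, n_plots):
    """Oracle: exhaustively enumerate all draws of occ_j plots."""
    marked = set(range(occ_i))
    hits = sum(
        1 for draw in combinations(range(n_plots), occ_j)
        if len(marked & set(draw)) >= shared
    )
    return hits / comb(n_plots, occ_j)


class TestPairNullTest:
    def test_zero_shared_is_certain(self):
        assert pair_null_test(0, 3, 4, 10) == 1.0

    def test_known_hand_value(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert pair_null_test(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_saturated_margin_forces_overlap(self):
        # occ_i = n_plots: every draw overlaps fully, so any feasible
        # threshold up to occ_j is certain
        for shared in range(5):
            assert pair_null_test(shared, 10, 4, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            occ_i = int(rng.integers(1, n + 1))
            occ_j = int(rng.integers(1, n + 1))
            lo = max(0, occ_i + occ_j - n)
            shared = int(rng.integers(lo, min(occ_i, occ_j) + 1))
            expect = enumerate_tail(shared, occ_i, occ_j, n)
            assert pair_null_test(shared, occ_i, occ_j, n) == pytest.approx(
                expect, rel=1e-10, abs=1e-12)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            pair_null_test(5, 4, 4, 10)
        with pytest.raises(ValueError):
            pair_null_test(1, 3, 11, 10)


def _edges(pvals):
    return [CooccurrenceEdge(f"a{i}", f"b{i}", 1, p) for i, p in enumerate(pvals)]


class TestFilterEdges:
    def test_all_null_pvalues_give_empty_set(self):
        assert filter_edges(_edges([1.0, 1.0, 1.0]), alpha=0.05) == []

    def test_bh_hand_ranks(self):
        # q = p * m / rank: 0.003, 0.03, 0.9 -> first two pass at 0.05
        kept = filter_edges(_edges([0.001, 0.02, 0.9]), alpha=0.05)
        assert [e.p_null for e in kept] == [0.001, 0.02]
        assert kept[0].q_value == pytest.approx(0.003)
        assert kept[1].q_value == pytest.approx(0.03)

    def test_alpha_one_none_keeps_all(self):
        edges = _edges([0.5, 0.99, 1.0])
        assert len(filter_edges(edges, alpha=1.0, method="none")) == 3

    def test_monotone_in_alpha(self, rng):
        edges = _edges(rng.random(40))
        prev = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            kept = {e.species_i for e in filter_edges(edges, alpha=alpha)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_empty_input_is_empty_not_error(self):
        assert filter_edges([], alpha=0.05) == []


def all_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def brute_force_max_q(graph):
    return max(
        nx.community.modularity(graph, [set(p) for p in part])
        for part in all_partitions(list(graph.nodes))
    )


class TestDetectModules:
    def test_two_cliques_split_with_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = detect_modules(g)
        labels = part.species_module
        assert len({labels[n] for n in range(4)}) == 1
        assert len({labels[n] for n in range(4, 8)}) == 1
        assert labels[0] != labels[4]
        assert part.modularity_q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        part = detect_modules(nx.complete_graph(6))
        assert len(set(part.species_module.values())) == 1

    @pytest.mark.parametrize("make", [
        lambda: nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
        lambda: nx.complete_graph(8),
        lambda: nx.Graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]),
        lambda: nx.cycle_graph(6),
        lambda: nx.path_graph(7),
    ], ids=["two_k4", "k8", "bridged_triangles", "cycle6", "path7"])
    def test_q_reaches_brute_force_maximum(self, make):
        g = make()
        part = detect_modules(g)
        assert part.modularity_q == pytest.approx(brute_force_max_q(g), abs=1e-9)

    def test_q_self_consistent_with_returned_partition(self):
        g = nx.planted_partition_graph(3, 10, 0.7, 0.05, seed=3)
        part = detect_modules(g)
        groups = {}
        for n, m in part.species_module.items():
            groups.setdefault(m, set()).add(n)
        q = nx.community.modularity(g, list(groups.values()))
        assert part.modularity_q == pytest.approx(q, abs=1e-12)

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(20):
            g = nx.planted_partition_graph(4, 15, 0.6, 0.02, seed=seed)
            part = detect_modules(g, seed=seed)
            truth = [g.nodes[n]["block"] for n in g]
            found = [part.species_module[n] for n in g]
            assert adjusted_rand_score(truth, found) >= 0.9

    def test_louvain_deterministic_given_seed(self):
        g = nx.planted_partition_graph(3, 12, 0.6, 0.05, seed=11)
        a = detect_modules(g, seed=5, method="louvain")
        b = detect_modules(g, seed=5, method="louvain")
        assert a.species_module == b.species_module

    def test_isolated_species_unassigned(self):
        g = nx.complete_graph(4)
        part = detect_modules(g, all_species=[0, 1, 2, 3, "lonely"])
        assert part.species_module["lonely"] == "unassigned"

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.raises(ValueError, match="relax"):
            detect_modules(g)


class TestPlotAndMainHabitat:
    def _inc(self, presence, plots=None, species=None):
        presence = np.asarray(presence, dtype=bool)
        plots = plots or [f"p{i}" for i in range(presence.shape[0])]
        species = species or [f"s{j}" for j in range(presence.shape[1])]
        return IncidenceMatrix(plots=plots, species=species, presence=presence)

    def test_majority_wins(self):
        inc = self._inc([[1, 1, 1]])
        labels = assign_plot_habitats(inc, {"s0": "1", "s1": "1", "s2": "2"})
        assert labels["p0"] == "1"

    def test_tie_breaks_to_larger_module(self):
        inc = self._inc([[1, 1, 0, 0]])
        # module 2 holds three species globally, module 1 only one
        modules = {"s0": "1", "s1": "2", "s2": "2", "s3": "2"}
        assert assign_plot_habitats(inc, modules)["p0"] == "2"

    def test_all_unassigned_plot(self):
        inc = self._inc([[1, 1]])
        labels = assign_plot_habitats(inc, {"s0": "unassigned", "s1": "unassigned"})
        assert labels["p0"] == "unassigned"

    def test_main_habitat_majority(self):
        assert assign_main_habitat({"1": 5, "2": 1, "3": 0}, {}) == "1"

    def test_main_habitat_tie_breaks_to_bigger_habitat(self):
        totals = {"1": 10, "2": 40}
        assert assign_main_habitat({"1": 3, "2": 3}, totals) == "2"

    def test_single_occurrence(self):
        assert assign_main_habitat({"7": 1}, {}) == "7"

    def test_no_labelled_occurrences(self):
        assert assign_main_habitat({}, {}) == "unassigned"
        assert assign_main_habitat({"unassigned": 4}, {}) == "unassigned"


class TestCooccurrenceEdges:
    def test_pvalues_match_pairwise_calls(self, rng):
        mat = rng.random((15, 6)) < 0.4
        mat[0] = True  # no empty plot
        inc = IncidenceMatrix(
            plots=[f"p{i}" for i in range(15)],
            species=[f"s{j}" for j in range(6)],
            presence=mat,
        )
        edges = cooccurrence_edges(inc)
        assert len(edges) == 15  # C(6,2)
        occ = {s: int(o) for s, o in zip(inc.species, inc.occupancy)}
        for e in edges:
            expect = pair_null_test(e.shared, occ[e.species_i],
                                    occ[e.species_j], inc.n_plots)
            assert e.p_null == pytest.approx(expect, rel=1e-12)
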