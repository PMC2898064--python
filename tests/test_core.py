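"""Shortest-path statistics, recurrence curves, and linker subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from finet.cancer import SampleAlterationTable
from finet.core import (
    asp_permutation_test,
    average_shortest_path,
    build_linker_subnetwork,
    cluster_genes_shortest_path,
    component_distances,
    degree_bins,
    recurrence_curve,
)


def path_graph(n):
    g = nx.path_graph(n)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


class TestAverageShortestPath:
    def test_complete_graph_is_one(self):
        g = nx.relabel_nodes(
            nx.complete_graph(5), {i: f"n{i}" for i in range(5)}
        )
        assert average_shortest_path(g, {"n0", "n3"}) == 1.0

    def test_p4_worked_example(self):
        g = path_graph(4)
        got = average_shortest_path(g, {"n0", "n1", "n2", "n3"})
        assert got == pytest.approx(10 / 6)

    def test_outside_component_excluded(self):
        g = path_graph(4)
        g.add_edge("x1", "x2")
        got = average_shortest_path(g, {"n0", "n3", "x1"})
        assert got == pytest.approx(3.0)

    def test_too_few_usable_genes(self):
        g = path_graph(4)
        g.add_edge("x1", "x2")
        with pytest.raises(ValueError):
            average_shortest_path(g, {"n0", "x1"})

    def test_adding_edges_never_increases_distance(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.15, seed=seed)
            comp = max(nx.connected_components(g), key=len)
            g = g.subgraph(comp).copy()
            g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
            _, d1 = component_distances(g)
            non_edges = [
                e for e in itertools.combinations(sorted(g.nodes), 2)
                if not g.has_edge(*e)
            ]
            if not non_edges:
                continue
            g2 = g.copy()
            g2.add_edge(*non_edges[0])
            _, d2 = component_distances(g2)
            assert (d2 <= d1 + 1e-9).all()


class TestDegreeStratifiedNull:
    def test_bins_reproduce_candidate_histogram(self, merged_net):
        from finet.network import largest_component

        comp = largest_component(merged_net)
        nodes = sorted(comp.nodes)
        degs = np.array([merged_net.degree(n) for n in nodes])
        hubs = [n for n, _ in sorted(
            comp.degree, key=lambda kv: -kv[1]
        )[:12]]
        cand_degs = [merged_net.degree(n) for n in hubs]
        bins = degree_bins(cand_degs, degs, min_pool=5)
        assert sum(c for _, _, c in bins) == len(cand_degs)
        for lo, hi, count in bins:
            pool = int(((degs >= lo) & (degs <= hi)).sum())
            assert pool >= count

    def test_degree_null_below_uniform_on_hubs(self, merged_net):
        """Hub-biased gene sets: degree-matched nulls sit closer together
        than uniform nulls (the direction of 2.86 < 3.83)."""
        from finet.network import largest_component

        comp = largest_component(merged_net)
        hubs = [n for n, _ in sorted(
            comp.degree, key=lambda kv: -kv[1]
        )[:15]]
        uni = asp_permutation_test(
            merged_net, hubs, "uniform", n_perm=200, seed=1
        )
        strat = asp_permutation_test(
            merged_net, hubs, "degree_stratified", n_perm=200, seed=1
        )
        assert strat.null_mean <= uni.null_mean

    def test_planted_clique_significant(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(80, 0.05, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        clique = [f"n{i:02d}" for i in range(8)]
        for a, b in itertools.combinations(clique, 2):
            g.add_edge(a, b)
        res = asp_permutation_test(g, clique, "uniform", n_perm=500, seed=4)
        assert res.n_as_short == 0
        assert res.p_str == "< 0.002"

    def test_unknown_mode_rejected(self, merged_net):
        with pytest.raises(ValueError):
            asp_permutation_test(merged_net, ["a", "b"], "bogus")


class TestRecurrence:
    def test_single_occurrence_cohort(self):
        cohort = SampleAlterationTable(
            samples={"s1": {"A"}, "s2": {"B"}}
        )
        curve = recurrence_curve(
            cohort, {"A", "B", "C"}, n_perm=20, seed=0
        )
        assert curve.observed[0] == 1.0
        assert len(curve.s_values) == 1  # nothing recurs

    def test_identical_samples_all_recur(self):
        cohort = SampleAlterationTable(
            samples={"s1": {"A", "B"}, "s2": {"A", "B"}}
        )
        curve = recurrence_curve(
            cohort, {"A", "B", "C", "D"}, n_perm=20, seed=0
        )
        assert curve.s_values == [1, 2]
        assert curve.observed[1] == 1.0

    def test_toy_cohort_matches_hand_tabulation(self):
        cohort = SampleAlterationTable(
            samples={
                "s1": {"A", "B"},
                "s2": {"B", "C"},
                "s3": {"B", "D"},
            }
        )
        curve = recurrence_curve(
            cohort, {"A", "B", "C", "D", "E"}, n_perm=20, seed=0
        )
        # B occurs 3x; A, C, D once -> >=1: 4/4, >=2: 1/4, >=3: 1/4
        assert curve.observed.tolist() == [1.0, 0.25, 0.25]

    def test_universe_must_cover_altered_genes(self):
        cohort = SampleAlterationTable(samples={"s1": {"A"}})
        with pytest.raises(ValueError):
            recurrence_curve(cohort, {"B"}, n_perm=5)


class TestGeneClustering:
    def _two_cliques(self, n1=8, n2=2, bridge_len=4):
        g = nx.Graph()
        a = [f"a{i}" for i in range(n1)]
        b = [f"b{i}" for i in range(n2)]
        for grp in (a, b):
            for x, y in itertools.combinations(grp, 2):
                g.add_edge(x, y)
        chain = [a[0]] + [f"m{i}" for i in range(bridge_len)] + [b[0]]
        for x, y in zip(chain, chain[1:]):
            g.add_edge(x, y)
        return g, a, b

    def test_dominant_clique_selected(self):
        g, a, b = self._two_cliques()
        got = cluster_genes_shortest_path(g, set(a) | set(b), coverage=0.7)
        assert got == set(a)

    def test_fully_adjacent_genes_return_everything(self):
        g = nx.relabel_nodes(
            nx.complete_graph(6), {i: f"n{i}" for i in range(6)}
        )
        got = cluster_genes_shortest_path(
            g, {"n0", "n1", "n2"}, coverage=0.5
        )
        assert got == {"n0", "n1", "n2"}

    def test_full_coverage_returns_root_with_warning(self):
        g, a, b = self._two_cliques()
        with pytest.warns(UserWarning):
            got = cluster_genes_shortest_path(
                g, set(a) | set(b), coverage=1.0
            )
        assert got == set(a) | set(b)

    def test_cluster_meets_coverage(self, merged_net):
        from finet.network import largest_component

        comp = largest_component(merged_net)
        nodes = sorted(comp.nodes)
        genes = set(nodes[::4][:40])
        got = cluster_genes_shortest_path(merged_net, genes, coverage=0.7)
        usable = genes & set(comp.nodes)
        assert len(got) > 0.7 * len(usable) or got == usable


class TestLinkerSubnetwork:
    def test_connected_candidates_need_no_linkers(self):
        g = nx.relabel_nodes(
            nx.complete_graph(4), {i: f"n{i}" for i in range(4)}
        )
        core = build_linker_subnetwork(g, {"n0", "n1", "n2"})
        assert core.linkers == set()
        assert nx.is_connected(core.graph)

    def test_path_interior_becomes_linker(self):
        g = path_graph(3)  # n0 - n1 - n2
        core = build_linker_subnetwork(g, {"n0", "n2"})
        assert core.linkers == {"n1"}

    def test_output_connected_and_covers_candidates(self, merged_net):
        from finet.network import largest_component

        comp = largest_component(merged_net)
        nodes = sorted(comp.nodes)
        cands = set(nodes[::7][:25])
        core = build_linker_subnetwork(merged_net, cands)
        assert nx.is_connected(core.graph)
        assert cands <= set(core.graph.nodes)
        assert not (core.linkers & core.candidates)

    def test_matches_bruteforce_minimum_on_tiny_graphs(self):
        """Greedy merge + pruning finds the exhaustive minimum number of
        connector genes on small random graphs."""

        def brute_min(g, cands):
            others = sorted(set(g.nodes) - set(cands))
            for size in range(len(others) + 1):
                for sub in itertools.combinations(others, size):
                    h = g.subgraph(set(cands) | set(sub))
                    if h.number_of_nodes() and nx.is_connected(h):
                        return size
            return None

        rng = np.random.default_rng(7)
        tested = 0
        while tested < 25:
            n = int(rng.integers(5, 9))
            p = float(rng.uniform(0.25, 0.5))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(10**6)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            comp = max(nx.connected_components(g), key=len, default=set())
            if len(comp) < 3:
                continue
            comp = sorted(comp)
            k = int(rng.integers(2, min(4, len(comp)) + 1))
            cands = list(rng.choice(comp, size=k, replace=False))
            core = build_linker_subnetwork(g, cands)
            assert len(core.linkers) == brute_min(g.subgraph(comp), cands)
            tested += 1

    def test_too_few_candidates_rejected(self):
        g = path_graph(3)
        with pytest.raises(ValueError):
            build_linker_subnetwork(g, {"n0"})
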