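"""Cohort analysis: modules, co-hit, sample clustering, enrichment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from finet.cancer import (
    ModulePartition,
    SampleAlterationTable,
    binary_distance_matrix,
    build_sample_module_matrix,
    cluster_samples,
    cohit_test,
    contingency_test,
    enrich_annotations,
    girvan_newman_modules,
    induce_alteration_subnetwork,
)
from finet.network import build_network
from finet.pathway import FunctionalInteraction


def fi(a, b):
    return FunctionalInteraction(pair=(a, b))


class TestSubnetworkInduction:
    def test_disjoint_genes_all_isolated(self):
        g = build_network([fi("A", "B")])
        sub, isolated = induce_alteration_subnetwork(g, {"X", "Y"})
        assert sub.number_of_nodes() == 0
        assert isolated == set()  # X, Y are not network nodes at all

    def test_isolated_gene_reported(self):
        g = build_network([fi("A", "B"), fi("C", "D")])
        sub, isolated = induce_alteration_subnetwork(g, {"A", "B", "C"})
        assert set(sub.edges) == {("A", "B")}
        assert isolated == {"C"}

    def test_full_gene_set_recovers_network(self):
        g = build_network([fi("A", "B"), fi("B", "C")])
        sub, isolated = induce_alteration_subnetwork(g, {"A", "B", "C"})
        assert set(sub.edges) == set(g.edges)
        assert isolated == set()


class TestGirvanNewman:
    def test_two_cliques_bridge(self, two_cliques_bridge):
        part = girvan_newman_modules(two_cliques_bridge)
        assert sorted(sorted(m) for m in part.modules) == [
            [f"n{i}" for i in range(5)],
            [f"n{i}" for i in range(5, 10)],
        ]

    def test_disconnected_components_separate(self):
        g = build_network([fi("A", "B"), fi("C", "D")])
        part = girvan_newman_modules(g)
        assert {frozenset(m) for m in part.modules} == {
            frozenset({"A", "B"}), frozenset({"C", "D"}),
        }

    def test_edgeless_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        part = girvan_newman_modules(g)
        assert sorted(part.sizes()) == [1, 1]

    def test_matches_reference_implementation(self):
        """Partition agrees with igraph's edge-betweenness community
        detection (equal-modularity cuts count as agreement)."""
        igraph = pytest.importorskip("igraph")

        def reference(g):
            nodes = sorted(g.nodes)
            idx = {n: i for i, n in enumerate(nodes)}
            h = igraph.Graph(
                n=len(nodes),
                edges=[(idx[a], idx[b]) for a, b in g.edges],
            )
            clus = h.community_edge_betweenness().as_clustering()
            part = sorted(
                (frozenset(nodes[v] for v in c) for c in clus),
                key=lambda m: (-len(m), sorted(m)),
            )
            return part, clus.modularity

        for seed in range(10):
            g = nx.gnp_random_graph(30, 0.12, seed=seed)
            g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
            mine = girvan_newman_modules(g).modules
            ref, ref_q = reference(g)
            my_q = nx.community.modularity(g, mine)
            assert mine == ref or my_q == pytest.approx(ref_q, abs=1e-9)

    def test_partition_properties(self, merged_net, study):
        genes = set(list(merged_net.nodes)[:60])
        sub, _ = induce_alteration_subnetwork(merged_net, genes)
        part = girvan_newman_modules(sub)
        covered = set()
        for m in part.modules:
            assert not (covered & m)
            covered |= m
        assert covered == set(sub.nodes)
        assert part.sizes() == sorted(part.sizes(), reverse=True)


class TestCohit:
    def _partition(self):
        return ModulePartition(
            modules=[frozenset({"A", "B", "E"}), frozenset({"C", "D"})]
        )

    def test_all_samples_hit_both(self):
        cohort = SampleAlterationTable(
            samples={"s1": {"A", "C"}, "s2": {"B", "D"}}
        )
        res = cohit_test(cohort, self._partition(), 0, 1, n_perm=50, seed=0)
        assert res.fraction == 1.0

    def test_half_samples_hit_both(self):
        cohort = SampleAlterationTable(
            samples={"s1": {"A"}, "s2": {"A", "C"}}
        )
        res = cohit_test(cohort, self._partition(), 0, 1, n_perm=50, seed=0)
        assert res.fraction == 0.5

    def test_extreme_observed_reported_below_resolution(self):
        # every sample hits both modules with singleton draws impossible
        cohort = SampleAlterationTable(
            samples={f"s{i}": {"A", "C"} for i in range(10)}
        )
        res = cohit_test(
            cohort, self._partition(), 0, 1, n_perm=200, seed=1
        )
        assert res.fraction == 1.0
        if res.n_as_extreme == 0:
            assert res.p_str.startswith("<")

    def test_matrix_construction(self):
        cohort = SampleAlterationTable(
            samples={"s1": {"A"}, "s2": {"C", "B"}}
        )
        mat = build_sample_module_matrix(cohort, self._partition())
        assert mat.loc["s1"].tolist() == [1, 0]
        assert mat.loc["s2"].tolist() == [1, 1]


class TestSampleClustering:
    def test_binary_distance_worked_example(self):
        mat = pd.DataFrame([[1, 1, 0], [1, 0, 1]])
        d = binary_distance_matrix(mat)
        assert d[0, 1] == pytest.approx(2 / 3)

    def test_all_zero_rows_distance_zero(self):
        mat = pd.DataFrame([[0, 0, 0], [0, 0, 0]])
        assert binary_distance_matrix(mat)[0, 1] == 0.0

    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
            index=["s1", "s2", "s3"],
        )
        labels, _ = cluster_samples(mat, k=2)
        assert labels["s1"] == labels["s2"] != labels["s3"]

    def test_cut_by_height(self):
        mat = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]], index=["a", "b", "c"]
        )
        labels, _ = cluster_samples(mat, height=0.5)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_exactly_one_cut_required(self):
        mat = pd.DataFrame([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            cluster_samples(mat)
        with pytest.raises(ValueError):
            cluster_samples(mat, height=0.5, k=2)


class TestContingency:
    def test_diagonal_half(self):
        assert contingency_test([[1, 0], [0, 1]], "hypergeometric") == (
            pytest.approx(0.5)
        )
        assert contingency_test([[1, 0], [0, 1]], "fisher") == (
            pytest.approx(0.5)
        )

    def test_perfect_association(self):
        expected = 1 / math.comb(10, 5)
        assert contingency_test([[5, 0], [0, 5]], "hypergeometric") == (
            pytest.approx(expected)
        )
        assert contingency_test([[5, 0], [0, 5]], "fisher") == (
            pytest.approx(expected)
        )

    def test_uniform_table_not_enriched(self):
        assert contingency_test([[5, 5], [5, 5]], "fisher") >= 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[0, 0], [0, 0]])


class TestEnrichment:
    def test_zero_hits_p_one(self):
        res = enrich_annotations(
            {"A", "B"},
            {"t": {"C", "D"}},
            {"A", "B", "C", "D"},
            n_perm=20,
            seed=0,
        )
        assert res[0].p_value == pytest.approx(1.0)

    def test_worked_binomial_value(self):
        # module of 4, background fraction 1/2, all four annotated
        universe = {f"g{i}" for i in range(8)}
        annotated = {"g0", "g1", "g2", "g3"}
        res = enrich_annotations(
            annotated, {"t": annotated}, universe, n_perm=50, seed=0
        )
        assert res[0].p_value == pytest.approx(0.0625, abs=1e-12)

    def test_matches_exact_binomial_summation(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(40)]
        annotations = {
            f"t{j}": {g for g in universe if rng.random() < 0.3}
            for j in range(6)
        }
        module = set(universe[:10])
        res = enrich_annotations(
            module, annotations, universe, n_perm=20, seed=2
        )
        for r in res:
            exact = sum(
                math.comb(r.n, x) * r.p_bg**x * (1 - r.p_bg) ** (r.n - x)
                for x in range(r.k, r.n + 1)
            )
            assert r.p_value == pytest.approx(exact, abs=1e-12)

    def test_fdr_bounds_and_monotonicity(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(50)]
        annotations = {
            f"t{j}": {g for g in universe if rng.random() < 0.25}
            for j in range(8)
        }
        module = set(universe[:12])
        res = enrich_annotations(
            module, annotations, universe, n_perm=200, seed=3
        )
        for r in res:
            assert 0.0 <= r.fdr <= 1.0
        by_p = sorted(res, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in by_p]
        assert fdrs == sorted(fdrs)

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_annotations({"X"}, {}, {"A"}, n_perm=5)

    def test_unknown_term_warned_and_skipped(self):
        with pytest.warns(UserWarning):
            res = enrich_annotations(
                {"A"}, {"t": {"Z"}}, {"A", "B"}, n_perm=5, seed=0
            )
        assert res == []
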