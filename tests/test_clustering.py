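"""Jaccard distances, UPGMA dendrograms, cluster testing, layered networks."""

import dendropy
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from cohortnet.clustering import (
    DistanceMatrix,
    build_layered_network,
    distance_matrix,
    fisher_exact_2x2,
    jaccard_distance,
    significant_clusters,
    unique_genes,
    upgma,
)
from cohortnet.errors import InputError
from cohortnet.io import Cohort
from cohortnet.networks import SampleNetwork

from oracles import fisher_2x2_enum


def net(sample_id, nodes, edges=(), seeds=None):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    seeds = frozenset(seeds if seeds is not None else nodes)
    return SampleNetwork(
        sample_id=sample_id, graph=g, seeds=seeds,
        imputed=frozenset(set(nodes) - seeds),
    )


node_sets = st.sets(st.sampled_from("abcdefghij"), min_size=0, max_size=8)


class TestJaccard:
    def test_identical_zero(self):
        assert jaccard_distance(net("x", "abc"), net("y", "abc")) == 0.0

    def test_disjoint_one(self):
        assert jaccard_distance(net("x", "ab"), net("y", "cd")) == 1.0

    def test_definition_arithmetic(self):
        assert jaccard_distance(net("x", "abc"), net("y", "bcd")) == pytest.approx(0.5)

    def test_both_empty_warns(self):
        with pytest.warns(UserWarning):
            assert jaccard_distance(net("x", ""), net("y", "")) == 1.0

    def test_edge_mode(self):
        a = net("x", "abc", edges=[("a", "b"), ("b", "c")])
        b = net("y", "abc", edges=[("a", "b")])
        assert jaccard_distance(a, b, on="edges") == pytest.approx(0.5)

    @given(a=node_sets, b=node_sets, c=node_sets)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_metric_properties(self, a, b, c):
        if not (a or b) or not (b or c) or not (a or c):
            return  # empty-vs-empty pairs are a warned degenerate case
        na, nb, nc = net("a", a), net("b", b), net("c", c)
        dab = jaccard_distance(na, nb)
        assert dab == jaccard_distance(nb, na)
        assert (dab == 0) == (a == b)
        assert dab <= jaccard_distance(na, nc) + jaccard_distance(nc, nb) + 1e-12


class TestUPGMA:
    def test_two_samples(self):
        dm = DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.4)
        assert tree.root.members == ("a", "b")

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            m = squareform(condensed)
            ids = [f"s{i:02d}" for i in range(n)]
            tree = upgma(DistanceMatrix(ids=ids, matrix=m))
            expected = squareform(cophenet(linkage(condensed, method="average")))
            np.testing.assert_allclose(tree.cophenetic_matrix(), expected, atol=1e-10)

    def test_ultrametric_heights(self):
        rng = np.random.default_rng(17)
        m = squareform(rng.uniform(0, 1, size=45))
        tree = upgma(DistanceMatrix(ids=[f"s{i}" for i in range(10)], matrix=m))
        for node in tree.internal_nodes():
            for child in node.children:
                assert tree.nodes[child].height <= node.height + 1e-12

    def test_equal_distances_tie_break_lexicographic(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0.0)
        tree = upgma(DistanceMatrix(ids=["c", "a", "b"], matrix=m))
        first_merge = tree.nodes[3]
        assert first_merge.members == ("a", "b")
        assert first_merge.height == pytest.approx(0.5)
        assert tree.root.height == pytest.approx(0.5)

    def test_nan_rejected(self):
        m = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(InputError):
            DistanceMatrix(ids=["a", "b"], matrix=m)

    def test_newick_parses_and_preserves_depths(self):
        rng = np.random.default_rng(3)
        m = squareform(rng.uniform(0.1, 1.0, size=15))
        ids = [f"s{i}" for i in range(6)]
        tree = upgma(DistanceMatrix(ids=ids, matrix=m))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(ids)
        # root-to-leaf distance equals the root merge height for every leaf
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(tree.root.height, abs=1e-9)


class TestFisher2x2:
    def test_forced_table(self):
        assert fisher_exact_2x2(0, 5, 0, 7) == 1.0
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_frozen_enumeration_value(self):
        # [[8,2],[1,9]] enumerates to 23/4199
        assert fisher_exact_2x2(8, 2, 1, 9) == pytest.approx(23 / 4199, abs=1e-12)

    def test_row_and_column_swap_invariance(self):
        p = fisher_exact_2x2(7, 2, 3, 8)
        assert fisher_exact_2x2(8, 3, 2, 7) == pytest.approx(p, abs=1e-12)

    def test_matches_enumeration_on_grid(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_2x2_enum(a, b, c, d), abs=1e-12
            )


class TestSignificantClusters:
    def _tree_and_cohort(self):
        # 8 cases cluster tightly; 8 controls likewise; cross distances large
        ids = [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)]
        n = len(ids)
        m = np.full((n, n), 0.9)
        m[:8, :8] = 0.1
        m[8:, 8:] = 0.1
        np.fill_diagonal(m, 0.0)
        status = {s: ("case" if s.startswith("A") else "control") for s in ids}
        tree = upgma(DistanceMatrix(ids=ids, matrix=m))
        return tree, Cohort(samples=ids, status=status)

    def test_two_pure_blocks_detected(self):
        tree, cohort = self._tree_and_cohort()
        results = significant_clusters(tree, cohort, min_size=3, alpha=0.05)
        maximal = [r for r in results if r.maximal]
        assert len(maximal) == 2
        doms = {r.dominance for r in maximal}
        assert doms == {"case", "control"}
        for r in maximal:
            assert r.p_value == pytest.approx(
                fisher_2x2_enum(r.n_cases, r.n_controls, 8 - r.n_cases, 8 - r.n_controls),
                abs=1e-12,
            )

    def test_min_size_larger_than_cohort(self):
        tree, cohort = self._tree_and_cohort()
        assert significant_clusters(tree, cohort, min_size=99) == []

    def test_proportional_cluster_not_significant(self):
        ids = [f"s{i}" for i in range(12)]
        status = {s: ("case" if i % 2 else "control") for i, s in enumerate(ids)}
        rng = np.random.default_rng(0)
        m = squareform(rng.uniform(0.4, 0.6, size=66))
        tree = upgma(DistanceMatrix(ids=ids, matrix=m))
        results = significant_clusters(tree, Cohort(samples=ids, status=status))
        assert all(not r.significant for r in results if abs(r.n_cases - r.n_controls) <= 1)

    def test_no_sample_in_two_maximal_clusters(self):
        tree, cohort = self._tree_and_cohort()
        results = significant_clusters(tree, cohort)
        seen = []
        for r in results:
            if r.maximal:
                seen.extend(r.members)
        assert len(seen) == len(set(seen)) <= len(cohort.samples)


class TestLayeredNetwork:
    def test_single_member_equals_network(self):
        n1 = net("s1", "abc", edges=[("a", "b")], seeds={"a", "b"})
        layer = build_layered_network(["s1"], {"s1": n1})
        assert layer.nodes == {"a", "b", "c"}
        assert all(layer.graph.nodes[x]["support"] == 1 for x in layer.graph.nodes)
        assert layer.role("c") == "imputed"

    def test_two_identical_members_double_support(self):
        n1 = net("s1", "ab", edges=[("a", "b")])
        n2 = net("s2", "ab", edges=[("a", "b")])
        layer = build_layered_network(["s1", "s2"], {"s1": n1, "s2": n2})
        assert layer.graph.nodes["a"]["support"] == 2
        assert layer.graph["a"]["b"]["support"] == 2

    def test_support_counts_match_recount(self):
        rng = np.random.default_rng(12)
        pool = list("abcdefghij")
        nets = {}
        for i in range(5):
            nodes = rng.choice(pool, size=4, replace=False)
            nets[f"s{i}"] = net(f"s{i}", nodes)
        layer = build_layered_network(nets.keys(), nets)
        for gene in layer.graph.nodes:
            recount = sum(1 for n in nets.values() if gene in n.nodes)
            assert layer.graph.nodes[gene]["support"] == recount

    def test_role_seed_wins_over_imputed(self):
        n1 = net("s1", "ab", seeds={"a"})   # b imputed here
        n2 = net("s2", "b", seeds={"b"})    # b seed here
        layer = build_layered_network(["s1", "s2"], {"s1": n1, "s2": n2})
        assert layer.role("b") == "seed"

    def test_missing_member_rejected(self):
        with pytest.raises(InputError):
            build_layered_network(["shadow"], {})


class TestUniqueGenes:
    def test_identical_layers_empty(self):
        n1 = net("s1", "abc")
        la = build_layered_network(["s1"], {"s1": n1})
        assert unique_genes(la, la) == ({}, {})

    def test_disjoint_layers_full(self):
        la = build_layered_network(["s1"], {"s1": net("s1", "ab")})
        lb = build_layered_network(["s2"], {"s2": net("s2", "cd")})
        ua, ub = unique_genes(la, lb)
        assert set(ua) == {"a", "b"} and set(ub) == {"c", "d"}

    def test_roles_annotated(self):
        la = build_layered_network(["s1"], {"s1": net("s1", "abc", seeds={"a"})})
        lb = build_layered_network(["s2"], {"s2": net("s2", "c")})
        ua, _ = unique_genes(la, lb)
        assert ua == {"a": "seed", "b": "imputed"}


def test_distance_matrix_orders_samples_lexicographically():
    nets = [net("z", "ab"), net("a", "ab"), net("m", "cd")]
    dm = distance_matrix(nets)
    assert dm.ids == ["a", "m", "z"]
    assert dm.matrix[0, 2] == 0.0 and dm.matrix[0, 1] == 1.0
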