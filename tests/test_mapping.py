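from itertools import combinations

import numpy as np
import pytest

from netfp.exceptions import ExternalToolError, FormatError, ParameterError
from netfp.graphio import build_network
from netfp.mapping import (AffinityMatrix, affinity_propagation,
                           build_affinity, greedy_align, merge_networks,
                           run_external_aligner)
from netfp.ontology import SimilarityMatrix


def sim_from(genes_a, genes_b, values):
    return SimilarityMatrix(tuple(genes_a), tuple(genes_b),
                            np.asarray(values, dtype=float), "precomputed")


class TestMerge:
    def test_threshold_rule(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        sim = sim_from(["a", "b"], ["x", "y"], [[0.9, 0.1], [0.1, 0.1]])
        mg = merge_networks(q, r, sim, tau=0.5)
        assert mg.n_cross_edges == 1
        assert mg.graph.has_edge("Q:a", "R:x")

    def test_unsatisfiable_threshold(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        sim = sim_from(["a", "b"], ["x", "y"], [[1.0, 1.0], [1.0, 1.0]])
        assert merge_networks(q, r, sim, tau=1.5).n_cross_edges == 0

    def test_identity_copy_gives_cross_edge_per_gene(self):
        q = build_network("q", [("a", "b"), ("b", "c")])
        eye = sim_from(sorted(q.nodes), sorted(q.nodes), np.eye(3))
        mg = merge_networks(q, q, eye, tau=0.5)
        assert mg.n_cross_edges == 3
        # origins partition the merged node set
        origins = {n[0] for n in mg.nodes}
        assert origins == {"Q", "R"} and len(mg.nodes) == 6


class TestBuildAffinity:
    def test_zero_topo_weight_equals_attr(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        sim = sim_from(["a", "b", "x", "y"], ["a", "b", "x", "y"],
                       np.full((4, 4), 0.3))
        mg = merge_networks(q, r, sim, tau=0.5)
        A = build_affinity(mg, sim, w_topo=0.0, preference=0.0)
        off = A.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.3)

    def test_identical_neighborhoods_full_topo(self):
        # a-c, b-c: nodes a and b have identical neighbor sets {c}
        q = build_network("q", [("a", "c"), ("b", "c")])
        r = build_network("r", [("x", "y")])
        zero = sim_from(["a", "b", "c", "x", "y"], ["a", "b", "c", "x", "y"],
                        np.zeros((5, 5)))
        mg = merge_networks(q, r, zero, tau=0.5)
        A = build_affinity(mg, zero, w_topo=1.0, preference=0.0)
        ia, ib = A.nodes.index("Q:a"), A.nodes.index("Q:b")
        assert A.matrix[ia, ib] == pytest.approx(1.0)

    def test_median_preference(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        # attr 0.1 for one unordered pair, 0.9 for another, w_topo=0 and the
        # remaining pairs complete the off-diagonal multiset symmetrically
        vals = np.zeros((4, 4))
        genes = ["a", "b", "x", "y"]
        pairs = {("a", "b"): 0.1, ("x", "y"): 0.9, ("a", "x"): 0.1,
                 ("a", "y"): 0.9, ("b", "x"): 0.5, ("b", "y"): 0.5}
        for (g1, g2), v in pairs.items():
            i, j = genes.index(g1), genes.index(g2)
            vals[i, j] = vals[j, i] = v
        sim = sim_from(genes, genes, vals)
        mg = merge_networks(q, r, sim, tau=2.0)
        A = build_affinity(mg, sim, w_topo=0.0, preference="median")
        assert np.allclose(np.diag(A.matrix), 0.5)


class TestAffinityPropagation:
    def test_single_node(self):
        m = affinity_propagation(AffinityMatrix(("a",), np.array([[0.5]])))
        assert len(m.clusters) == 1 and m.clusters[0].exemplar == "a"

    def test_two_block_example(self):
        S = np.full((4, 4), 0.1)
        S[0, 1] = S[1, 0] = 0.9
        S[2, 3] = S[3, 2] = 0.9
        np.fill_diagonal(S, 0.5)
        m = affinity_propagation(AffinityMatrix(("n1", "n2", "n3", "n4"), S))
        groups = sorted(sorted(c.members) for c in m.clusters)
        assert groups == [["n1", "n2"], ["n3", "n4"]]

    def test_high_preference_gives_singletons(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(3, 9))
            S = rng.uniform(0, 0.5, (n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 0.95)
            m = affinity_propagation(AffinityMatrix(tuple(map(str, range(n))), S))
            assert all(len(c.members) == 1 for c in m.clusters)

    def test_empty_error(self):
        with pytest.raises(ParameterError):
            affinity_propagation(AffinityMatrix((), np.zeros((0, 0))))

    def test_partition_and_exemplar_membership(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0, 1, (10, 10))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0.4)
        m = affinity_propagation(AffinityMatrix(tuple(map(str, range(10))), S))
        assert m.all_nodes == frozenset(map(str, range(10)))
        for c in m.clusters:
            assert c.exemplar in c.members

    def test_near_optimal_on_block_matrices(self):
        """AP net similarity within 5% of exhaustive exemplar-set optimum."""
        def net_sim(S, ex):
            total = sum(S[k, k] for k in ex)
            for i in range(len(S)):
                if i not in ex:
                    total += max(S[i, k] for k in ex)
            return total

        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            S = rng.uniform(0, 0.2, (n, n))
            for block in (range(0, n // 2), range(n // 2, n)):
                for i in block:
                    for j in block:
                        if i != j:
                            S[i, j] = rng.uniform(0.7, 0.9)
            S = (S + S.T) / 2
            np.fill_diagonal(S, 0.3)
            m = affinity_propagation(AffinityMatrix(tuple(map(str, range(n))), S))
            ap_val = net_sim(S, {int(c.exemplar) for c in m.clusters})
            opt = max(net_sim(S, set(c))
                      for r in range(1, n + 1)
                      for c in combinations(range(n), r))
            assert ap_val >= 0.95 * opt


class TestGreedyAlign:
    def test_identity_pairs_each_gene_with_copy(self):
        q = build_network("q", [("a", "b"), ("b", "c")])
        eye = sim_from(sorted(q.nodes), sorted(q.nodes), np.eye(3))
        m = greedy_align(q, q, eye, min_sim=0.5)
        paired = {frozenset(c.members) for c in m.clusters if len(c.members) == 2}
        assert paired == {frozenset({f"Q:{g}", f"R:{g}"}) for g in "abc"}

    def test_forced_greedy_order(self):
        q = build_network("q", [("a1", "a2")])
        r = build_network("r", [("b1", "b2")])
        sim = sim_from(["a1", "a2"], ["b1", "b2"], [[0.9, 0.2], [0.8, 0.7]])
        m = greedy_align(q, r, sim, min_sim=0.5)
        pairs = {frozenset(c.members) for c in m.clusters if len(c.members) == 2}
        assert pairs == {frozenset({"Q:a1", "R:b1"}), frozenset({"Q:a2", "R:b2"})}

    def test_all_below_threshold_gives_singletons(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        sim = sim_from(["a", "b"], ["x", "y"], np.full((2, 2), 0.1))
        m = greedy_align(q, r, sim, min_sim=0.5)
        assert all(len(c.members) == 1 for c in m.clusters)
        assert m.all_nodes == {"Q:a", "Q:b", "R:x", "R:y"}

    def test_order_invariance_via_tie_break(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        ties = sim_from(["a", "b"], ["x", "y"], np.full((2, 2), 0.8))
        m = greedy_align(q, r, ties, min_sim=0.5)
        pairs = {frozenset(c.members) for c in m.clusters if len(c.members) == 2}
        # lexicographic: (a,x) first, then (b,y)
        assert pairs == {frozenset({"Q:a", "R:x"}), frozenset({"Q:b", "R:y"})}


class TestExternalAligner:
    def test_fixture_adapter(self, tmp_path):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        fixture = tmp_path / "clusters.txt"
        fixture.write_text("Q:a R:x\nQ:b R:y\n")
        template = f"cp {fixture} {{output}}"
        m = run_external_aligner(template, q, r)
        multi = [c for c in m.clusters if len(c.members) > 1]
        assert len(multi) == 2

    def test_nonzero_exit_raises(self):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        with pytest.raises(ExternalToolError):
            run_external_aligner("false # {query} {reference} {output}", q, r)

    def test_omitted_node_becomes_singleton(self, tmp_path):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        fixture = tmp_path / "clusters.txt"
        fixture.write_text("Q:a R:x\n")
        m = run_external_aligner(f"cp {fixture} {{output}}", q, r)
        singles = {next(iter(c.members)) for c in m.clusters if len(c.members) == 1}
        assert singles == {"Q:b", "R:y"}

    def test_unknown_node_is_format_error(self, tmp_path):
        q = build_network("q", [("a", "b")])
        r = build_network("r", [("x", "y")])
        fixture = tmp_path / "clusters.txt"
        fixture.write_text("Q:a R:zzz\n")
        with pytest.raises(FormatError):
            run_external_aligner(f"cp {fixture} {{output}}", q, r)
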