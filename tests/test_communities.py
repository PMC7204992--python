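import itertools

import networkx as nx
import pytest

from conftest import make_network
from oracles import brute_girvan_newman_best_q, partition_modularity
from rnscore import communities
from rnscore.communities import TermDAG
from rnscore.errors import ValidationError

TRIANGLES = [("a", "b"), ("b", "c"), ("a", "c"),
             ("x", "y"), ("y", "z"), ("x", "z"),
             ("c", "x")]  # bridge


def all_partitions(items):
    """Every partition of a small set (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestGirvanNewman:
    def test_two_triangles_with_bridge(self):
        out = communities.girvan_newman(make_network(TRIANGLES))
        assert sorted(sorted(m) for m in out.modules) == [["a", "b", "c"],
                                                          ["x", "y", "z"]]
        # optimum over *all* partitions of the 6 nodes agrees
        best = max(
            partition_modularity(TRIANGLES, [set(p) for p in part])
            for part in all_partitions("abcxyz")
        )
        assert out.modularity == pytest.approx(best)

    def test_single_clique_stays_whole(self):
        edges = [(a, b) for a, b in itertools.combinations("abcd", 2)]
        out = communities.girvan_newman(make_network(edges))
        assert [sorted(m) for m in out.modules] == [["a", "b", "c", "d"]]

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_dendrogram_level_oracle(self, trial):
        import numpy as np

        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(6, 13))
        g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(0, 2**31)))
        g.remove_nodes_from([v for v, d in g.degree if d == 0])
        if g.number_of_edges() < 2:
            pytest.skip("degenerate draw")
        edges = list(g.edges)
        out = communities.girvan_newman(make_network(edges))
        # oracle: independent GN replay with brute-force edge betweenness
        best = brute_girvan_newman_best_q(edges, list(g.nodes))
        assert out.modularity == pytest.approx(best, abs=1e-9)

    def test_modularity_bounds(self):
        out = communities.girvan_newman(make_network(TRIANGLES))
        assert -0.5 <= out.modularity <= 1.0
        assert out.modularity > 0  # bridge-separable planted structure


CHAIN_DAG = TermDAG(
    parents={"a": [], "b": [("a", "is_a")], "c": [("b", "is_a")]},
    annotations={"g1": frozenset({"c"}), "g2": frozenset({"b"}),
                 "g3": frozenset({"c"}), "g4": frozenset({"a"})},
)


class TestSemanticSimilarity:
    def test_identical_annotations_score_one(self):
        assert communities.semantic_similarity("g1", "g3", CHAIN_DAG) == pytest.approx(1.0)
        assert communities.semantic_similarity("g1", "g3", CHAIN_DAG,
                                               method="jaccard") == 1.0

    def test_wang_chain_hand_value(self):
        # S-values: c → {c:1, b:0.8, a:0.64}; b → {b:1, a:0.8}
        # shared {a, b}: (0.8+1) + (0.64+0.8) = 3.24; SV sum = 2.44+1.8 = 4.24
        expected = 3.24 / 4.24
        assert communities.term_similarity("c", "b", CHAIN_DAG) == pytest.approx(expected)
        assert communities.semantic_similarity("g1", "g2", CHAIN_DAG) == pytest.approx(expected)

    def test_root_only_overlap_is_low(self):
        dag = TermDAG(
            parents={"r": [], "p": [("r", "is_a")], "q": [("r", "is_a")]},
            annotations={"g1": frozenset({"p"}), "g2": frozenset({"q"})},
        )
        sim = communities.semantic_similarity("g1", "g2", dag)
        # only the root is shared: (0.8+0.8)/(1.8+1.8)
        assert sim == pytest.approx(1.6 / 3.6)
        assert sim < 0.5

    def test_unannotated_gene_gives_none(self):
        assert communities.semantic_similarity("g1", "nope", CHAIN_DAG) is None

    def test_cyclic_dag_rejected(self):
        with pytest.raises(ValidationError):
            TermDAG(parents={"a": [("b", "is_a")], "b": [("a", "is_a")]},
                    annotations={})


class TestDetectModules:
    def coherent_dag(self, genes_a, genes_b):
        parents = {"R": [], "MA": [("R", "is_a")], "MB": [("R", "is_a")]}
        ann = {}
        for g in genes_a:
            ann[g] = frozenset({"MA"})
        for g in genes_b:
            ann[g] = frozenset({"MB"})
        return TermDAG(parents=parents, annotations=ann)

    def test_all_similar_keeps_gn_partition(self):
        dag = self.coherent_dag("abc", "xyz")
        net = make_network(TRIANGLES)
        out = communities.detect_modules(net, dag, sim_threshold=0.5, min_size=3)
        assert sorted(sorted(m) for m in out.modules) == [["a", "b", "c"],
                                                          ["x", "y", "z"]]

    def test_incoherent_module_dissolves(self):
        # triangle abc functionally split: its edges fall below threshold
        dag = self.coherent_dag("a", "bxyz")
        dag.annotations["c"] = frozenset()  # drop c → treated as unannotated
        dag = TermDAG(parents=dag.parents,
                      annotations={g: t for g, t in dag.annotations.items() if t})
        net = make_network(TRIANGLES)
        out = communities.detect_modules(net, dag, sim_threshold=0.9, min_size=3)
        # a–b edge has low similarity and is cut; c is unannotated so its
        # edges survive; xyz stays coherent
        assert ["x", "y", "z"] in [sorted(m) for m in out.modules]
        for m in out.modules:
            assert len(m) >= 3

    def test_zero_threshold_is_noop_filter(self):
        dag = self.coherent_dag("abc", "xyz")
        net = make_network(TRIANGLES)
        gn = communities.girvan_newman(net)
        out = communities.detect_modules(net, dag, sim_threshold=0.0, min_size=3)
        assert sorted(sorted(m) for m in out.modules) == sorted(
            sorted(m) for m in gn.modules
        )

    def test_modules_disjoint_and_min_size(self):
        dag = self.coherent_dag("abc", "xyz")
        out = communities.detect_modules(make_network(TRIANGLES), dag,
                                         sim_threshold=0.5, min_size=3)
        seen = set()
        for m in out.modules:
            assert len(m) >= 3
            assert not (m & seen)
            seen |= m
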