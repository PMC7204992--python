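import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import make_network
from oracles import brute_topology
from rnscore import netscore
from rnscore.errors import ParameterError, PipelineError


class TestTopology:
    def test_path_graph_hand_values(self, path_graph):
        t = netscore.topology(path_graph)
        assert t.loc["B", "K"] == 2
        assert t.loc["B", "L"] == pytest.approx(1.0)
        assert t.loc["A", "L"] == pytest.approx(1.5)
        assert t.loc["A", "CC"] == pytest.approx(2 / 3)
        assert t.loc["B", "BC"] == pytest.approx(1.0)
        assert t.loc["A", "BC"] == pytest.approx(0.0)

    def test_complete_graph_symmetry(self):
        net = make_network([(a, b) for a in "ABCD" for b in "ABCD" if a < b])
        t = netscore.topology(net)
        assert (t["L"] == 1.0).all()
        assert (t["CC"] == 1.0).all()
        assert (t["BC"] == 0.0).all()
        assert (t["K"] == 3).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 31))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(0, 2**31)))
        g.remove_nodes_from([v for v, d in g.degree if d == 0])
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        net = make_network(list(g.edges))
        table = netscore.topology(net)
        oracle = brute_topology(list(g.edges), list(g.nodes))
        for v in g.nodes:
            for col in ("K", "L", "BC", "CC"):
                assert table.loc[v, col] == pytest.approx(oracle[v][col]), (v, col)

    def test_star_graph_hub_profile(self):
        """The hub maximizes K and BC but minimizes L: RNs down-weights it."""
        net = make_network([("HUB", f"L{i}") for i in range(6)])
        t = netscore.topology(net)
        assert t.loc["HUB", "K"] == t["K"].max()
        assert t.loc["HUB", "BC"] == t["BC"].max()
        assert t.loc["HUB", "L"] == t["L"].min()
        rs = {g: 0.5 for g in t.index}
        scores = netscore.rns(t, rs)
        assert scores["HUB"] == scores.min()


class TestRns:
    def test_formula_values(self):
        topo = pd.DataFrame({"K": [4, 1], "L": [2.0, 1.5]}, index=["a", "b"])
        scores = netscore.rns(topo, {"a": 0.5, "b": 1.0})
        assert scores["a"] == pytest.approx(2.0 * 0.5 / 4)
        assert scores["b"] == pytest.approx(1.5 * 1.0 / 1)

    def test_doubling_degree_halves_score(self):
        t1 = pd.DataFrame({"K": [2], "L": [1.5]}, index=["g"])
        t2 = pd.DataFrame({"K": [4], "L": [1.5]}, index=["g"])
        assert netscore.rns(t2, {"g": 0.8})["g"] == pytest.approx(
            netscore.rns(t1, {"g": 0.8})["g"] / 2
        )

    def test_monotonicity_in_each_argument(self):
        base = netscore.rns(pd.DataFrame({"K": [3], "L": [2.0]}, index=["g"]),
                            {"g": 0.5})["g"]
        more_l = netscore.rns(pd.DataFrame({"K": [3], "L": [2.5]}, index=["g"]),
                              {"g": 0.5})["g"]
        more_rs = netscore.rns(pd.DataFrame({"K": [3], "L": [2.0]}, index=["g"]),
                               {"g": 0.9})["g"]
        more_k = netscore.rns(pd.DataFrame({"K": [5], "L": [2.0]}, index=["g"]),
                              {"g": 0.5})["g"]
        assert more_l > base and more_rs > base and more_k < base

    def test_empty_intersection_is_pipeline_error(self):
        topo = pd.DataFrame({"K": [1], "L": [1.0]}, index=["a"])
        with pytest.raises(PipelineError):
            netscore.rns(topo, {"b": 1.0})


class TestConsensus:
    def series(self, **kv):
        return pd.Series(kv)

    def test_support_counting_and_selection(self):
        t1 = self.series(a=1.0, b=0.9, c=0.1)
        t2 = self.series(a=0.8, d=0.7, c=0.2)
        t3 = self.series(e=0.5, f=0.4, g=0.3)
        out = netscore.consensus([t1, t2, t3], top_k=2, min_datasets=2)
        assert out.loc["a", "support"] == 2 and out.loc["a", "selected"]
        assert out.loc["b", "support"] == 1 and not out.loc["b", "selected"]
        assert out.loc["a", "mean_rns"] == pytest.approx(0.9)

    def test_identical_tables_idempotent(self):
        t = self.series(a=0.9, b=0.8, c=0.7, d=0.1)
        out = netscore.consensus([t, t, t], top_k=3, min_datasets=2)
        assert set(out.index[out["selected"]]) == {"a", "b", "c"}
        assert (out["support"] == 3).all()

    def test_top_k_larger_than_table_warns_and_uses_all(self, caplog):
        t = self.series(a=0.9, b=0.8)
        with caplog.at_level("WARNING"):
            out = netscore.consensus([t, t], top_k=10, min_datasets=2)
        assert len(out) == 2

    def test_min_datasets_validation(self):
        t = self.series(a=1.0)
        with pytest.raises(ParameterError):
            netscore.consensus([t], top_k=1, min_datasets=2)

    def test_deterministic_tie_break_order(self):
        t1 = self.series(a=0.5, b=0.5, c=0.5)
        out = netscore.consensus([t1, t1], top_k=2, min_datasets=2)
        # ties by RNs resolve lexicographically: a, b enter the top-2
        assert list(out.index) == ["a", "b"]
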