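import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import microstand as ms


def spearman_brute(x, y):
    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        t = pd.DataFrame([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]],
                         index=["up1", "up2", "down"])
        rho, _ = ms.spearman_matrix(t)
        assert rho.loc["up1", "up2"] == pytest.approx(1.0)
        assert rho.loc["up1", "down"] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, rng):
        t = pd.DataFrame([[3, 1, 4, 1, 5], [2, 7, 1, 8, 2]], index=["x", "y"])
        rho, _ = ms.spearman_matrix(t)
        assert rho.loc["x", "y"] == pytest.approx(
            spearman_brute([3, 1, 4, 1, 5], [2, 7, 1, 8, 2]), abs=1e-12)
        for _ in range(20):
            t = pd.DataFrame(rng.integers(0, 10, size=(4, 5)))
            rho, _ = ms.spearman_matrix(t)
            for i, j in itertools.combinations(range(4), 2):
                ref = spearman_brute(t.iloc[i], t.iloc[j])
                if np.isnan(ref):
                    assert np.isnan(rho.iloc[i, j])
                else:
                    assert rho.iloc[i, j] == pytest.approx(ref, abs=1e-12)

    def test_constant_feature_is_nan(self):
        t = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["c", "v"])
        rho, p = ms.spearman_matrix(t)
        assert np.isnan(rho.loc["c", "v"])

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            ms.spearman_matrix(pd.DataFrame([[1, 2, 3], [3, 2, 1]]))


class TestBuildCooccurrence:
    def _rel(self, rng, n_feat=30, n_samp=20):
        t = pd.DataFrame(rng.integers(1, 100, size=(n_feat, n_samp)),
                         index=[f"F{i}" for i in range(n_feat)])
        return ms.to_relative(t)

    def test_unreachable_rho_gives_no_edges(self, rng):
        net = ms.build_cooccurrence(self._rel(rng), min_abund=0.0, rho_min=1.01)
        assert net.number_of_edges() == 0
        assert all(d["isolated"] for _, d in net.nodes(data=True))

    def test_abundance_floor_is_strict(self):
        rel = pd.DataFrame({"S%d" % i: [0.5, 0.3, 0.199, 0.001] for i in range(6)},
                           index=["A", "B", "C", "D"])
        net = ms.build_cooccurrence(rel, min_abund=0.2, rho_min=0.0, q_max=1.0)
        assert set(net.nodes) == {"A", "B"}  # C at 0.199 < 0.2; D well below

    def test_edge_attributes_and_sign(self, rng):
        x = np.arange(10, dtype=float)
        rel = pd.DataFrame([x + 1, 2 * x + 3, 20 - x, rng.uniform(size=10)],
                           index=["a", "b", "c", "noise"])
        rel = rel / rel.sum()
        net = ms.build_cooccurrence(rel, min_abund=0.0, rho_min=0.9, q_max=0.05)
        assert net["a"]["b"]["sign"] == "positive"
        assert net["a"]["c"]["sign"] == "negative"
        assert 0 <= net["a"]["b"]["q_value"] <= 0.05

    def test_too_few_nodes_is_an_error(self, rng):
        rel = self._rel(rng)
        with pytest.raises(ValueError, match="min_abund"):
            ms.build_cooccurrence(rel, min_abund=1.0)


class TestTopologyAndModules:
    def test_triangle_and_star_statistics(self):
        tri = nx.Graph()
        tri.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], sign="positive")
        s = ms.topology_summary(tri)
        assert (s["n_nodes"], s["n_edges"], s["density"], s["mean_degree"]) == (3, 3, 1.0, 2.0)
        star = nx.star_graph(4)
        s = ms.topology_summary(star)
        assert s["mean_degree"] == pytest.approx(8 / 5)
        empty = nx.empty_graph(5)
        assert ms.topology_summary(empty)["density"] == 0.0

    def test_disjoint_cliques_recovered_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(4))
        g = nx.relabel_nodes(g, str)
        modules = ms.assign_modules(g)
        assert len(set(modules.values())) == 2
        for comp in nx.connected_components(g):
            assert len({modules[n] for n in comp}) == 1
        single = nx.relabel_nodes(nx.complete_graph(5), str)
        assert len(set(ms.assign_modules(single).values())) == 1

    def test_bridged_blocks_recovered_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        g = nx.relabel_nodes(g, str)
        planted = [0] * 6 + [1] * 6
        for seed in range(20):
            modules = ms.assign_modules(g, seed=seed, method="louvain")
            detected = [modules[str(i)] for i in range(12)]
            assert adjusted_rand_score(planted, detected) >= 0.8

    def test_isolated_nodes_get_singleton_modules(self):
        g = nx.relabel_nodes(nx.complete_graph(3), str)
        g.add_node("loner")
        modules = ms.assign_modules(g)
        assert sum(m == modules["loner"] for m in modules.values()) == 1


class TestZiPi:
    def _two_module_graph(self):
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a1", "a3"), ("a2", "a3")])
        g.add_edges_from([("b1", "b2"), ("b1", "b3"), ("b2", "b3")])
        modules = {n: "A" if n.startswith("a") else "B" for n in g.nodes}
        return g, modules

    def test_internal_node_has_pi_zero(self):
        g, modules = self._two_module_graph()
        zipi = ms.zi_pi(g, modules)
        assert (zipi["pi"] == 0.0).all()

    def test_even_split_gives_pi_half(self):
        g, modules = self._two_module_graph()
        g.add_node("hub")
        modules["hub"] = "A"
        g.add_edges_from([("hub", "a1"), ("hub", "a2"), ("hub", "b1"), ("hub", "b2")])
        zipi = ms.zi_pi(g, modules)
        assert zipi.loc["hub", "pi"] == pytest.approx(0.5, abs=1e-15)
        # direct-formula check for every node
        for node in g.nodes:
            k = g.degree(node)
            if k == 0:
                continue
            per = {}
            for nb in g[node]:
                per[modules[nb]] = per.get(modules[nb], 0) + 1
            assert zipi.loc[node, "pi"] == pytest.approx(
                1 - sum((v / k) ** 2 for v in per.values()), abs=1e-15)

    def test_uniform_module_degree_gives_zi_zero(self):
        g, modules = self._two_module_graph()
        zipi = ms.zi_pi(g, modules)
        assert (zipi["zi"] == 0.0).all()  # cliques: every sd is 0

    def test_degree_zero_node_convention(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        g.add_edge("y", "z")
        modules = {"x": "M1", "y": "M2", "z": "M2"}
        zipi = ms.zi_pi(g, modules)
        roles = ms.classify_roles(zipi)
        assert zipi.loc["x", "pi"] == 0.0 and zipi.loc["x", "zi"] == 0.0
        assert roles.loc["x", "role"] == "peripheral"

    def test_pi_strictly_below_one(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        g = nx.relabel_nodes(g, str)
        modules = ms.assign_modules(g)
        zipi = ms.zi_pi(g, modules)
        assert (zipi["pi"] < 1.0).all()
        assert ((zipi["pi"] == 0) == (zipi.apply(
            lambda r: all(modules[nb] == r["module"] for nb in g[r.name]),
            axis=1))).all()


class TestClassifyRoles:
    @pytest.mark.parametrize("zi,pi,role", [
        (3.0, 0.50, "module_hub"),
        (3.0, 0.70, "network_hub"),
        (1.0, 0.30, "peripheral"),
        (1.0, 0.70, "connector"),
        (2.5, 0.62, "peripheral"),   # boundary equality falls low
        (2.5, 0.70, "connector"),
        (3.0, 0.62, "module_hub"),
    ])
    def test_threshold_quadrants(self, zi, pi, role):
        df = pd.DataFrame({"zi": [zi], "pi": [pi]}, index=["n"])
        assert ms.classify_roles(df).loc["n", "role"] == role

    def test_every_node_exactly_one_role(self, rng):
        df = pd.DataFrame({"zi": rng.normal(2.5, 1, 100),
                           "pi": rng.uniform(0, 1, 100)})
        roles = ms.classify_roles(df)
        assert roles["role"].isin(
            ["module_hub", "network_hub", "connector", "peripheral"]).all()
        assert len(roles) == 100
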