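"""Network construction filters and topology diagnostics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ceranet import (
    build_network,
    closeness,
    degree_summary,
    fit_power_law,
    graph_from_edge_list,
    pearson_with_p,
    shortest_path_histogram,
    topology_summary,
)
from tests._oracles import (
    closeness_bfs,
    graph_to_adj,
    ols_loglog,
    path_histogram_bfs,
    pearson_formula,
)


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pearson_with_p([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = 0.4 * x + rng.normal(size=30)
            r, p = pearson_with_p(x, y)
            r0, p0 = pearson_formula(x, y)
            assert r == pytest.approx(r0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_p([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="length"):
            pearson_with_p([1, 2], [1, 2])


def _de_table(rows):
    return pd.DataFrame(rows, columns=["molecule_id", "class", "status"])


def _pairs(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])


class TestBuildNetwork:
    @pytest.fixture
    def toy(self, matrix_factory, rng):
        """mir_a correlates with lnc1 and gene1; mir_b only with lnc2."""
        n = 60
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        def noisy(base, sign=1.0):
            return np.maximum(0.05, 5.0 + sign * base + 0.35 * rng.normal(size=n))
        vals = np.vstack([
            noisy(z1), noisy(-z1), noisy(-z1),      # mir_a, lnc1, gene1
            noisy(z2), noisy(-z2),                   # mir_b, lnc2
            rng.uniform(1, 2, n),                    # gene2: uncorrelated
        ])
        m = matrix_factory(
            vals,
            classes=["miRNA", "lncRNA", "mRNA", "miRNA", "lncRNA", "mRNA"],
        )
        m.values.index = ["mir_a", "lnc1", "gene1", "mir_b", "lnc2", "gene2"]
        m.molecule_class.index = m.values.index
        return m

    def toy_inputs(self, statuses=None):
        statuses = statuses or {}
        de = _de_table([
            (m, c, statuses.get(m, "up"))
            for m, c in [("mir_a", "miRNA"), ("lnc1", "lncRNA"),
                         ("gene1", "mRNA"), ("mir_b", "miRNA"),
                         ("lnc2", "lncRNA"), ("gene2", "mRNA")]
        ])
        pairs = _pairs([
            ("mir_a", "lnc1", "lncRNA"), ("mir_a", "gene1", "mRNA"),
            ("mir_b", "lnc2", "lncRNA"), ("mir_b", "gene2", "mRNA"),
        ])
        return de, pairs

    def test_shared_mirna_rule_removes_one_sided_mirna(self, toy):
        de, pairs = self.toy_inputs()
        net = build_network(de, pairs, toy)
        # mir_b's mRNA pair (gene2) is uncorrelated, so mir_b keeps only a
        # lncRNA edge and is removed entirely by step 3
        assert set(net.graph.nodes) == {"mir_a", "lnc1", "gene1"}
        assert net.graph.number_of_edges() == 2

    def test_non_de_mirna_excluded(self, toy):
        de, pairs = self.toy_inputs({"mir_a": "not_de"})
        net = build_network(de, pairs, toy)
        assert "mir_a" not in net.graph.nodes
        assert net.graph.number_of_edges() == 0

    def test_row_order_invariance(self, toy):
        de, pairs = self.toy_inputs()
        a = build_network(de, pairs, toy)
        b = build_network(
            de.iloc[::-1].reset_index(drop=True),
            pairs.iloc[::-1].reset_index(drop=True),
            toy,
        )
        assert set(map(tuple, a.edges[["mirna_id", "target_id"]].values)) == \
            set(map(tuple, b.edges[["mirna_id", "target_id"]].values))

    def test_threshold_monotonicity(self, toy):
        de, pairs = self.toy_inputs()
        loose = build_network(de, pairs, toy, r_cut=0.3, p_cut=0.05)
        tight = build_network(de, pairs, toy, r_cut=0.5, p_cut=0.01)
        loose_edges = set(map(tuple, loose.edges[["mirna_id", "target_id"]].values))
        tight_edges = set(map(tuple, tight.edges[["mirna_id", "target_id"]].values))
        assert tight_edges <= loose_edges

    def test_unknown_molecule_skipped_with_warning(self, toy, caplog):
        de, pairs = self.toy_inputs()
        pairs.loc[len(pairs)] = ("mir_a", "ghost", "mRNA")
        de.loc[len(de)] = ("ghost", "mRNA", "up")
        import logging
        with caplog.at_level(logging.WARNING, logger="ceranet.network"):
            net = build_network(de, pairs, toy)
        assert "ghost" not in net.graph.nodes
        assert any("ghost" in r.message for r in caplog.records)

    def test_tripartite_and_all_de_invariants(self, cohort, de_calls):
        from ceranet import collapse_to_pairs, filter_by_clip

        pairs = collapse_to_pairs(
            filter_by_clip(cohort.candidates, cohort.clip_sites)
        )
        net = build_network(de_calls, pairs, cohort.combined)
        de_ids = set(de_calls.loc[de_calls["status"] != "not_de", "molecule_id"])
        for node, data in net.graph.nodes(data=True):
            assert node in de_ids
            assert net.graph.degree(node) >= 1
        for u, v in net.graph.edges:
            cu, cv = net.graph.nodes[u]["cls"], net.graph.nodes[v]["cls"]
            assert (cu == "miRNA") != (cv == "miRNA")
        assert (net.edges["r"].abs() > 0.4).all()
        assert (net.edges["p_value"] < 0.01).all()
        by_mirna = net.edges.groupby("mirna_id")["target_class"].agg(set)
        assert all({"lncRNA", "mRNA"} <= s for s in by_mirna)


class TestDegreeSummary:
    def test_star_and_triangle(self):
        star = nx.star_graph(4)  # hub degree 4 + 4 leaves
        out = degree_summary(star)
        assert out["frac_degree_lt"] == 1.0
        tri = nx.complete_graph(3)
        out = degree_summary(tri)
        assert out["frac_degree_gt"] == 0.0
        assert out["histogram"] == {2: 3}

    def test_matches_recount_oracle(self, rng):
        g = nx.gnp_random_graph(200, 0.03, seed=4)
        out = degree_summary(g)
        degs = [sum(1 for _ in g[v]) for v in g]
        assert out["frac_degree_lt"] == sum(d < 5 for d in degs) / 200
        assert out["frac_degree_gt"] == sum(d > 10 for d in degs) / 200
        assert sum(out["histogram"].values()) == 200

    def test_empty_graph_error(self):
        with pytest.raises(ValueError, match="empty"):
            degree_summary(nx.Graph())


class TestPowerLaw:
    def test_exact_power_law(self):
        hist = {k: 100 * k**-2 for k in range(1, 6)}
        out = fit_power_law(hist)
        assert out["slope"] == pytest.approx(-2.0)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["correlation"] == pytest.approx(1.0)

    def test_uniform_slope_zero(self):
        out = fit_power_law({k: 7 for k in range(1, 6)})
        assert out["slope"] == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        hist = {int(k): int(f) for k, f in
                zip(range(1, 12), rng.integers(1, 60, 11))}
        out = fit_power_law(hist)
        slope, r2 = ols_loglog(hist)
        assert out["slope"] == pytest.approx(slope, abs=1e-10)
        assert out["r_squared"] == pytest.approx(r2, abs=1e-10)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_power_law({1: 5, 2: 3})


class TestPaths:
    def test_path_graph(self):
        g = nx.path_graph(3)
        out = shortest_path_histogram(g)
        assert out["histogram"] == {1: 2, 2: 1}
        assert out["disconnected_pairs"] == 0

    def test_two_disjoint_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        out = shortest_path_histogram(g)
        assert out["histogram"] == {1: 2}
        assert out["disconnected_pairs"] == 4

    def test_matches_bfs_oracle(self):
        g = nx.gnp_random_graph(50, 0.06, seed=9)
        out = shortest_path_histogram(g)
        hist, disc = path_histogram_bfs(graph_to_adj(g))
        assert out["histogram"] == hist
        assert out["disconnected_pairs"] == disc


class TestCloseness:
    def test_path_and_complete(self):
        c = closeness(nx.path_graph(3))
        assert c[1] == pytest.approx(1.0)
        assert c[0] == pytest.approx(2 / 3)
        assert all(v == pytest.approx(1.0)
                   for v in closeness(nx.complete_graph(4)).values())

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("a")
        assert closeness(g)["a"] == 0.0

    def test_matches_bfs_oracle(self):
        g = nx.gnp_random_graph(60, 0.05, seed=3)
        got = closeness(g)
        expected = closeness_bfs(graph_to_adj(g))
        for v in g:
            assert got[v] == pytest.approx(expected[v], abs=1e-12)


def test_topology_summary_and_external_edge_list(tmp_path):
    edges = pd.DataFrame(
        [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")],
        columns=["source", "target"],
    )
    g = graph_from_edge_list(edges, classes={"a": "miRNA"})
    topo = topology_summary(g)
    assert topo["n_nodes"] == 4
    assert topo["n_edges"] == 4
    assert topo["class_counts"]["miRNA"] == 1
    assert topo["degree"]["histogram"] == {1: 1, 2: 2, 3: 1}
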