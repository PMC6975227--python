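"""Clique-extension modules, 1-D k-means, Kaplan-Meier, log-rank, screen."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ceranet import (
    clique_extension_clusters,
    km_curve,
    kmeans_two_groups,
    logrank,
    maximal_cliques,
    module_score,
    survival_screen,
)
from tests._oracles import (
    km_product_limit,
    kmeans_1d_best_split_objective,
    logrank_tabulation,
    maximal_cliques_brute,
)


class TestMaximalCliques:
    def test_triangle_plus_pendant(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        cliques = set(maximal_cliques(g))
        assert cliques == {frozenset("abc"), frozenset("cd")}

    def test_complete_graph(self):
        assert maximal_cliques(nx.complete_graph(4)) == [frozenset(range(4))]

    def test_matches_brute_force(self):
        g = nx.gnp_random_graph(15, 0.4, seed=8)
        adj = {v: set(g[v]) for v in g}
        assert set(maximal_cliques(g)) == maximal_cliques_brute(adj)


class TestCliqueExtension:
    def test_vertex_joins_when_ratio_reaches_threshold(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("d", "a"), ("d", "b")])
        mods = clique_extension_clusters(g, threshold=0.6, min_size=3)
        assert len(mods) == 1
        assert mods[0].nodes == frozenset("abcd")  # d: 2/3 >= 0.6
        assert mods[0].additions == (("d", 2 / 3),)

    def test_vertex_with_one_neighbor_stays_out(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("d", "a")])
        mods = clique_extension_clusters(g, threshold=0.6, min_size=3)
        assert mods[0].nodes == frozenset("abc")  # d: 1/3 < 0.6

    def test_two_overlapping_cliques_stay_distinct(self):
        # two 4-cliques sharing one vertex; hand-run: no outside vertex of
        # either clique reaches ratio 2/4 >= 0.6, so both stand as-is
        g = nx.Graph()
        for block in ("abcd", "defg"):
            g.add_edges_from(
                (x, y) for i, x in enumerate(block) for y in block[i + 1:]
            )
        mods = clique_extension_clusters(g, threshold=0.6, min_size=3)
        assert {m.nodes for m in mods} == {frozenset("abcd"), frozenset("defg")}

    def test_subset_modules_deduplicated(self):
        g = nx.complete_graph(5)
        mods = clique_extension_clusters(g, threshold=0.6, min_size=3)
        assert len(mods) == 1
        assert len(mods[0]) == 5

    def test_bipartite_graph_yields_no_triangle_modules(self):
        # star-shaped miRNA-target graphs cannot grow at threshold 0.6
        g = nx.star_graph(5)
        assert clique_extension_clusters(g, threshold=0.6, min_size=3) == []

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            clique_extension_clusters(nx.complete_graph(3), threshold=0.0)

    def test_relabeling_invariance(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("d", "a"), ("d", "b")])
        relabel = {"a": "x1", "b": "x2", "c": "x3", "d": "x4"}
        h = nx.relabel_nodes(g, relabel)
        mods_g = clique_extension_clusters(g, 0.6, 3)
        mods_h = clique_extension_clusters(h, 0.6, 3)
        assert [{relabel[n] for n in m.nodes} for m in mods_g] == [
            set(m.nodes) for m in mods_h
        ]

    def test_extension_audit_replayable(self):
        g = nx.gnp_random_graph(30, 0.3, seed=2)
        for m in clique_extension_clusters(g, threshold=0.6, min_size=3):
            grown = set(m.nodes) - {n for n, _ in m.additions}
            for node, ratio in m.additions:
                expected = sum(1 for u in g[node] if u in grown) / len(grown)
                assert ratio == pytest.approx(expected)
                assert ratio >= 0.6
                grown.add(node)


class TestModuleScore:
    def test_single_molecule_standardized(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0, 3.0, 4.0]])
        s = module_score(["g0"], m)
        v = np.array([1, 2, 3, 4], float)
        assert s.values == pytest.approx((v - v.mean()) / v.std())

    def test_opposite_profiles_cancel(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert module_score(["g0", "g1"], m).values == pytest.approx([0, 0, 0])

    def test_raw_mode_matches_column_mean_oracle(self, matrix_factory, rng):
        vals = rng.uniform(0, 8, (6, 10))
        m = matrix_factory(vals)
        s = module_score([f"g{i}" for i in range(6)], m, standardize=False)
        assert s.values == pytest.approx(vals.mean(axis=0))

    def test_missing_molecule_named(self, matrix_factory):
        with pytest.raises(KeyError, match="ghost"):
            module_score(["ghost"], matrix_factory([[1.0, 2.0]]))


class TestKMeans:
    def test_well_separated(self):
        labels = kmeans_two_groups([0.9, 1.0, 1.1, 4.8, 5.0, 5.2])
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_two_distinct_values(self):
        labels = kmeans_two_groups([1.0, 5.0, 1.0, 5.0])
        assert labels.tolist() == [0, 1, 0, 1]

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_two_groups([2.0, 2.0, 2.0])

    def test_objective_reaches_best_threshold_split(self, rng):
        for _ in range(20):
            s = np.concatenate([
                rng.normal(0, 1, 30), rng.normal(rng.uniform(0.5, 4), 1, 30)
            ])
            labels = kmeans_two_groups(s, seed=0)
            obj = sum(
                ((s[labels == k] - s[labels == k].mean()) ** 2).sum()
                for k in (0, 1)
            )
            assert obj <= kmeans_1d_best_split_objective(s) + 1e-8


class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        km = km_curve([1, 2, 3], [1, 1, 1])
        by_t = dict(zip(km["time"], km["survival"]))
        assert by_t[1.0] == pytest.approx(2 / 3)
        assert by_t[2.0] == pytest.approx(1 / 3)
        assert by_t[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        km = km_curve([5, 6, 7], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_mixed_matches_hand_table(self):
        time = [2, 3, 3, 5, 8, 9]
        event = [1, 1, 0, 1, 0, 1]
        km = km_curve(time, event)
        by_t = dict(zip(km["time"], km["survival"]))
        for t, s in km_product_limit(time, event):
            assert by_t[t] == pytest.approx(s)

    def test_nonincreasing_starts_at_one(self, rng):
        time = rng.exponential(100, 40)
        event = (rng.random(40) < 0.7).astype(int)
        km = km_curve(time, event)
        assert km["survival"].iloc[0] <= 1.0 + 1e-12
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_negative_time_error(self):
        with pytest.raises(ValueError, match="negative"):
            km_curve([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        chi2, p = logrank([1] * 6, [1] * 6, [2] * 6, [0] * 6)
        assert p < 0.05

    def test_symmetry_under_group_swap(self, rng):
        ta, tb = rng.exponential(50, 20), rng.exponential(100, 20)
        ea = (rng.random(20) < 0.8).astype(int)
        eb = (rng.random(20) < 0.8).astype(int)
        assert logrank(ta, ea, tb, eb) == pytest.approx(logrank(tb, eb, ta, ea))

    def test_matches_tabulation_oracle(self, rng):
        for _ in range(10):
            ta = np.round(rng.exponential(60, 20), 1)
            tb = np.round(rng.exponential(110, 20), 1)
            ea = (rng.random(20) < 0.75).astype(int)
            eb = (rng.random(20) < 0.75).astype(int)
            chi2, p = logrank(ta, ea, tb, eb)
            chi2_o, p_o = logrank_tabulation(ta, ea, tb, eb)
            assert chi2 == pytest.approx(chi2_o, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(p_o, rel=1e-9, abs=1e-12)

    def test_requires_events_and_nonempty(self):
        with pytest.raises(ValueError, match="event"):
            logrank([1, 2], [0, 0], [3, 4], [0, 0])
        with pytest.raises(ValueError, match="nonempty"):
            logrank([], [], [1], [1])


class TestSurvivalScreen:
    def test_planted_module_flagged(self, cohort):
        res = survival_screen(
            {"planted": cohort.ledger.prognostic_module},
            cohort.combined, cohort.clinical, seed=0,
        )
        assert res[0].significant
        assert res[0].direction == "low"  # module-low samples fare worse

    def test_degenerate_unit_reported_others_run(self, cohort):
        const_id = cohort.combined.molecules[0]
        expr = cohort.combined
        expr.values.loc[const_id] = 1.0  # constant profile
        res = survival_screen(
            {"bad": [const_id], "good": cohort.ledger.prognostic_module},
            expr, cohort.clinical, seed=0,
        )
        by_id = {r.unit_id: r for r in res}
        assert by_id["bad"].error is not None
        assert by_id["good"].error is None

    def test_too_few_clinical_samples_error(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(0).uniform(1, 5, (3, 8)))
        clin = pd.DataFrame(
            {"sample_id": ["s0", "s1"], "time_days": [10, 20], "event": [1, 0]}
        )
        with pytest.raises(ValueError, match=">= 10 tumor samples"):
            survival_screen({"u": ["g0"]}, m, clin)
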