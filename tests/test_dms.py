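"""Greedy module search, score normalization, ranking and merging."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_weighted_graph
from densegwas.dms import (
    Module,
    SearchParams,
    build_search_graph,
    grow_module,
    merge_modules,
    module_log10_pvalue,
    module_pvalue,
    module_score,
    modules_from_frame,
    modules_to_frame,
    normalize_scores,
    null_score_stats,
    rank_and_select,
    search_all,
)
from densegwas.errors import ConfigError, DomainError

PARAMS = SearchParams(r=0.1, d=1, n_random=1000, rng_seed=0)


def greedy_oracle(graph, seed, r, d):
    """Independent step-by-step re-simulation of the stated greedy rule.

    Brute force: at each step enumerate every node within graph distance d of
    the module, score each candidate's inclusion from scratch, take the
    maximizer (lexicographic tie-break), accept iff Z_new > Z_old * (1 + r).
    Returns the member set, the final score, and the accepted (old, new)
    score pairs.
    """
    z = nx.get_node_attributes(graph, "z")

    def score(nodes):
        return sum(z[n] for n in nodes) / math.sqrt(len(nodes))

    members = {seed}
    steps = []
    while True:
        dist = nx.multi_source_dijkstra_path_length(graph, members, cutoff=d, weight=None)
        cand = sorted(n for n, dd in dist.items() if n not in members and dd <= d)
        if not cand:
            break
        best = max(cand, key=lambda n: (score(members | {n}), [-ord(c) for c in n]))
        old, new = score(members), score(members | {best})
        if new > old * (1 + r):
            members.add(best)
            steps.append((old, new))
        else:
            break
    return members, score(members), steps


class TestModuleScore:
    def test_singleton_identity(self):
        assert module_score([2.0]) == 2.0

    def test_four_equal_weights(self):
        assert module_score([1.0, 1.0, 1.0, 1.0]) == pytest.approx(2.0)

    def test_mixed_signs(self):
        assert module_score([3.0, -1.0]) == pytest.approx(2.0 / math.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            module_score([])


class TestGrowModule:
    def test_low_seed_absorbs_strong_neighbor(self, path_graph_ab):
        m = grow_module(path_graph_ab, "A", PARAMS)
        assert m.genes == ("A", "B")
        assert m.Zm == pytest.approx(4.0 / math.sqrt(2))

    def test_strong_seed_refuses_expansion(self, path_graph_ab):
        # 4/sqrt(2) = 2.83 < 3 * 1.1: expansion refused
        m = grow_module(path_graph_ab, "B", PARAMS)
        assert m.genes == ("B",)
        assert m.Zm == 3.0

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("S", z=1.7)
        m = grow_module(g, "S", PARAMS)
        assert m.genes == ("S",) and m.Zm == 1.7

    def test_unweighted_seed_rejected(self):
        g = nx.Graph()
        g.add_node("X")
        with pytest.raises(DomainError):
            grow_module(g, "X", PARAMS)

    @pytest.mark.parametrize("trial", range(10))
    @pytest.mark.parametrize("d", [1, 2])
    def test_matches_brute_force_oracle(self, trial, d):
        rng = np.random.default_rng(1000 + trial)
        g = random_weighted_graph(rng)
        params = SearchParams(r=0.1, d=d, n_random=1000, rng_seed=0)
        for seed in sorted(g):
            mod = grow_module(g, seed, params)
            members, score, steps = greedy_oracle(g, seed, params.r, d)
            assert set(mod.genes) == members
            assert mod.Zm == pytest.approx(score, rel=1e-9)
            for old, new in steps:
                assert new > old * (1 + params.r)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(77)
        g = random_weighted_graph(rng)
        c = 3.7
        g2 = g.copy()
        nx.set_node_attributes(
            g2, {n: c * g.nodes[n]["z"] for n in g}, "z"
        )
        for seed in sorted(g):
            m1 = grow_module(g, seed, PARAMS)
            m2 = grow_module(g2, seed, PARAMS)
            assert m1.genes == m2.genes
            assert m2.Zm == pytest.approx(c * m1.Zm, rel=1e-9)

    def test_seed_containment_and_connectivity(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = random_weighted_graph(rng)
            for seed in sorted(g):
                m = grow_module(g, seed, PARAMS)
                assert m.seed in m.genes
                assert nx.is_connected(g.subgraph(m.genes))


class TestSearchAll:
    def test_one_module_per_weighted_seed(self):
        g = random_weighted_graph(np.random.default_rng(3), n_max=5)
        modules = search_all(g, PARAMS)
        assert len(modules) == g.number_of_nodes()
        assert [m.seed for m in modules] == sorted(g)

    def test_identical_gene_sets_keep_distinct_seeds(self):
        g = nx.Graph([("A", "B")])
        nx.set_node_attributes(g, {"A": 1.0, "B": 1.0}, "z")
        modules = search_all(g, PARAMS)
        # both seeds absorb the other node (2/sqrt(2) > 1.1)
        assert {m.seed for m in modules} == {"A", "B"}
        assert all(set(m.genes) == {"A", "B"} for m in modules)


class TestBuildSearchGraph:
    def test_excluded_and_unscored_genes_removed(self):
        scores = pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D"],
                "p_g": [0.5, 0.5, 1e-14, 0.5],
                "z": [0.0, 0.0, 7.7, np.nan],
                "excluded": [False, False, True, False],
            }
        )
        g = build_search_graph([("A", "B"), ("B", "C"), ("C", "D")], scores)
        assert set(g) == {"A", "B"}

    def test_small_components_dropped_isolated_weighted_kept(self):
        scores = pd.DataFrame(
            {
                "gene": list("ABCDEF"),
                "p_g": [0.5] * 6,
                "z": [1.0] * 6,
                "excluded": [False] * 6,
            }
        )
        # big component A-B-C, small component D-E, F not in the edge list
        g = build_search_graph([("A", "B"), ("B", "C"), ("D", "E")], scores)
        assert set(g) == {"A", "B", "C"}


class TestNormalizeScores:
    def test_degenerate_equal_weights_raise(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        nx.set_node_attributes(g, {n: 2.0 for n in g}, "z")
        modules = [Module(seed="A", genes=("A", "B"), Zm=module_score([2.0, 2.0]))]
        with pytest.raises(DomainError, match="k=2"):
            normalize_scores(modules, g, PARAMS)

    def test_null_normalization_mean_zero_sd_one(self):
        # random sets scored then standardized by their own null statistics
        rng = np.random.default_rng(1)
        weights = rng.normal(size=500)
        stats_by_k = null_score_stats(weights, [8], n_random=10_000, rng_seed=1)
        mean8, sd8 = stats_by_k[8]
        draws = np.array(
            [
                weights[rng.choice(500, 8, replace=False)].sum() / math.sqrt(8)
                for _ in range(4000)
            ]
        )
        zn = (draws - mean8) / sd8
        assert abs(zn.mean()) < 0.05
        assert abs(zn.std() - 1.0) < 0.1

    def test_normalization_is_seeded_and_deterministic(self):
        g = random_weighted_graph(np.random.default_rng(9))
        modules = search_all(g, PARAMS)
        a, stats_a = normalize_scores(modules, g, PARAMS)
        b, stats_b = normalize_scores(modules, g, PARAMS)
        assert stats_a == stats_b
        assert [m.Zn for m in a] == [m.Zn for m in b]


class TestModulePvalue:
    def test_zero_is_half(self):
        assert module_pvalue(0.0) == 0.5

    def test_paper_scale_bounds(self):
        assert module_pvalue(11.13) < 2.20e-16
        assert module_pvalue(7.66) <= 2.04e-14

    def test_matches_high_precision_complement(self):
        # oracle: mpmath-free high-precision via erfc identity with scipy's
        # independent erfc implementation
        from scipy import special

        for zn in np.linspace(0.0, 15.0, 61):
            oracle = 0.5 * special.erfc(zn / math.sqrt(2))
            assert module_pvalue(zn) == pytest.approx(oracle, rel=1e-12)

    def test_log10_tail_accurate_deep(self):
        # at Zn = 40 the p-value underflows in double precision but its log10
        # must stay finite; oracle = Mills-ratio asymptotic expansion
        z = 40.0
        asymptotic = (-z * z / 2 - math.log(z * math.sqrt(2 * math.pi))) / math.log(10)
        assert module_log10_pvalue(z) == pytest.approx(asymptotic, abs=0.01)
        assert module_pvalue(z) == 0.0


class TestRankAndSelect:
    @staticmethod
    def fake_modules(n, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        return [
            Module(seed=f"S{i:05d}", genes=(f"S{i:05d}",), Zm=1.0, Zn=float(rng.normal()), pm=0.5)
            for i in range(n)
        ]

    def test_top_one_percent_of_7458_is_75(self):
        assert len(rank_and_select(self.fake_modules(7458), 0.01)) == 75

    def test_top_one_percent_of_7566_is_76(self):
        assert len(rank_and_select(self.fake_modules(7566), 0.01)) == 76

    def test_top_n_override(self):
        modules = self.fake_modules(10)
        top = rank_and_select(modules, top_n=3)
        zns = sorted((m.Zn for m in modules), reverse=True)
        assert [m.Zn for m in top] == zns[:3]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            rank_and_select(self.fake_modules(5), top_fraction=0.0)


class TestMergeModules:
    def graph(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        nx.set_node_attributes(g, {n: 1.0 for n in g}, "z")
        return g

    def test_disjoint_modules(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        nx.set_node_attributes(g, {n: 1.0 for n in g}, "z")
        merged = merge_modules(
            [Module("A", ("A", "B"), 1.0), Module("C", ("C", "D"), 1.0)], g
        )
        assert merged.number_of_nodes() == 4 and merged.number_of_edges() == 2

    def test_induced_union_includes_cross_edges(self):
        merged = merge_modules(
            [Module("A", ("A", "B"), 1.0), Module("B", ("B", "C"), 1.0)], self.graph()
        )
        assert ("A", "C") in merged.edges or ("C", "A") in merged.edges

    def test_membership_counts(self):
        merged = merge_modules(
            [Module("A", ("A", "B"), 1.0), Module("B", ("B", "C"), 1.0)], self.graph()
        )
        assert merged.nodes["B"]["n_modules"] == 2
        assert merged.nodes["A"]["n_modules"] == 1

    def test_single_module_identity(self):
        g = self.graph()
        merged = merge_modules([Module("A", ("A", "B", "C"), 1.0)], g)
        assert set(merged.edges) == set(g.subgraph({"A", "B", "C"}).edges)


class TestModuleTableRoundTrip:
    def test_frame_round_trip(self, tmp_path):
        modules = [
            Module("A", ("A", "B"), 2.1213203435596424, Zn=1.5, pm=0.0668),
            Module("C", ("C",), -0.25, Zn=None, pm=None),
        ]
        frame = modules_to_frame(modules)
        path = tmp_path / "modules.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
        back = modules_from_frame(pd.read_csv(path, sep="\t"))
        assert [m.seed for m in back] == ["A", "C"]
        assert back[0].genes == ("A", "B")
        assert back[0].Zm == pytest.approx(modules[0].Zm, rel=1e-12)
        assert back[1].Zn is None
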