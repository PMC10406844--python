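"""Null-model architecture statistics: ensembles, modularity, keystones."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micronet import (
    AbundanceTable,
    cnm_modularity,
    degree_preserved_modularity_null,
    er_consistency_test,
    keystone_summary,
    ks_two_sample,
    mean_degree,
    sample_gnm,
)
from micronet.architecture import _double_edge_swaps, _ks_batch


def modularity_of(graph, membership):
    m = graph.number_of_edges()
    q = 0.0
    clusters = set(membership.values())
    for c in clusters:
        nodes = [v for v, cc in membership.items() if cc == c]
        sub = graph.subgraph(nodes)
        lc = sub.number_of_edges()
        dc = sum(d for _, d in graph.degree(nodes))
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def best_partition_exhaustive(graph):
    """Oracle: enumerate all set partitions of <= 8 nodes."""
    nodes = list(graph.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [smaller[i] + [head]] + smaller[i + 1:]
            yield [[head]] + smaller

    best = -1.0
    for part in partitions(nodes):
        membership = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, modularity_of(graph, membership))
    return best


class TestSampleGnm:
    def test_full_edge_budget_gives_complete_graph(self):
        g = sample_gnm(5, 10, seed=0)
        assert nx.is_isomorphic(g, nx.complete_graph(5))

    def test_exact_edge_count_every_draw(self):
        for seed in range(20):
            g = sample_gnm(10, 13, seed=seed)
            assert g.number_of_edges() == 13
            assert g.number_of_nodes() == 10
            assert sum(d for _, d in g.degree) == 26

    def test_infeasible_spec(self):
        with pytest.raises(ValueError, match="infeasible"):
            sample_gnm(4, 7, seed=0)

    def test_uniform_over_all_graphs(self):
        # G(4, 2): 15 equally likely graphs; chi-square goodness of fit
        rng = np.random.default_rng(42)
        counts = {}
        for _ in range(15_000):
            g = sample_gnm(4, 2, seed=int(rng.integers(1 << 31)))
            key = tuple(sorted(tuple(sorted(e)) for e in g.edges))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        p = stats.chisquare(np.array(list(counts.values()))).pvalue
        assert p > 0.01


class TestKsTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_disjoint_small_samples_exact(self):
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings

    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a = rng.integers(0, 8, size=rng.integers(11, 30))
            b = rng.integers(0, 8, size=rng.integers(11, 30))
            res = ks_two_sample(a, b)
            grid = np.unique(np.concatenate([a, b]))
            brute = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in grid
            )
            assert res.statistic == pytest.approx(brute, abs=1e-12)

    def test_batch_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 6, size=40)
        b = rng.integers(0, 9, size=60)
        d, p = _ks_batch(b[None, :], a)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d[0] == pytest.approx(ref.statistic, abs=1e-12)
        # same Smirnov family; scipy applies a finite-n continuity tweak
        assert p[0] == pytest.approx(ref.pvalue, rel=0.2, abs=0.02)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            ks_two_sample([], [1, 2])


class TestErConsistency:
    def test_null_graph_is_consistent(self):
        # graph itself drawn from G(101, 121): high fraction of p > 0.05
        g = sample_gnm(101, 121, seed=3)
        res = er_consistency_test(g, n_replicates=500, seed=4)
        assert res.frac_p_above_alpha >= 0.90
        assert res.verdict

    def test_star_is_flagged(self):
        star = nx.star_graph(100)  # 101 nodes, 100 edges
        res = er_consistency_test(star, n_replicates=500, seed=5)
        assert res.frac_p_above_alpha <= 0.05
        assert not res.verdict

    def test_same_seed_identical_pvalues(self):
        g = sample_gnm(30, 45, seed=6)
        r1 = er_consistency_test(g, n_replicates=100, seed=7)
        r2 = er_consistency_test(g, n_replicates=100, seed=7)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_ensemble_summaries(self):
        g = sample_gnm(20, 30, seed=8)
        res = er_consistency_test(g, n_replicates=200, seed=9)
        assert res.samples.size == 200
        assert 0.0 <= res.ci_lower <= res.ci_upper <= 1.0
        assert 0.0 <= res.frac_p_above_alpha <= 1.0


class TestCnmModularity:
    def test_two_disjoint_triangles(self, two_triangles):
        part = cnm_modularity(two_triangles)
        assert part.q == pytest.approx(0.5)
        assert part.n_clusters == 2
        assert part.q == pytest.approx(
            best_partition_exhaustive(two_triangles)
        )

    def test_bridged_triangles(self, bridged_triangles):
        part = cnm_modularity(bridged_triangles)
        assert part.q == pytest.approx(5.0 / 14.0)
        assert part.q == pytest.approx(
            best_partition_exhaustive(bridged_triangles)
        )
        clusters = {
            frozenset(v for v, c in part.membership.items() if c == cc)
            for cc in set(part.membership.values())
        }
        assert clusters == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_single_clique_q_zero(self):
        part = cnm_modularity(nx.complete_graph(5))
        assert part.q == pytest.approx(0.0, abs=1e-12)
        assert part.n_clusters == 1

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(10)
        for _ in range(8):
            g = sample_gnm(7, int(rng.integers(4, 12)), seed=int(rng.integers(1 << 31)))
            g = g.subgraph([v for v, d in g.degree if d > 0]).copy()
            if g.number_of_edges() == 0:
                continue
            part = cnm_modularity(g)
            assert part.q <= best_partition_exhaustive(g) + 1e-12

    def test_matches_networkx_greedy_q(self, two_triangles):
        communities = nx.community.greedy_modularity_communities(
            two_triangles
        )
        q_nx = nx.community.modularity(two_triangles, communities)
        assert cnm_modularity(two_triangles).q == pytest.approx(q_nx)

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError, match="no edges"):
            cnm_modularity(nx.empty_graph(4))


class TestDegreePreservedNull:
    def test_swaps_preserve_degree_sequence_every_replicate(self):
        g = sample_gnm(30, 60, seed=11)
        base = [tuple(e) for e in g.edges]
        degrees = sorted(d for _, d in g.degree)
        rng = np.random.default_rng(12)
        for _ in range(20):
            rewired, accepted = _double_edge_swaps(
                base, rng, n_swaps=600, max_attempts=60_000
            )
            counts = {}
            for u, v in rewired:
                assert u != v
                counts[u] = counts.get(u, 0) + 1
                counts[v] = counts.get(v, 0) + 1
            assert sorted(counts.values()) == [d for d in degrees if d > 0]
            assert len({frozenset(e) for e in rewired}) == len(rewired)

    def test_planted_two_cliques_exceed_null(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        res = degree_preserved_modularity_null(
            g, n_replicates=1000, seed=13
        )
        assert res.empirical_statistic > res.ci_upper
        assert res.verdict

    def test_random_graphs_rarely_exceed_null(self):
        exceed = 0
        for i in range(50):
            g = sample_gnm(100, 150, seed=1000 + i)
            g = g.subgraph([v for v, d in g.degree if d > 0]).copy()
            res = degree_preserved_modularity_null(
                g, n_replicates=200, seed=i
            )
            exceed += res.verdict
        assert exceed <= 5  # <= 10% of 50 trials

    def test_star_has_no_swaps(self):
        star = nx.star_graph(6)
        res = degree_preserved_modularity_null(
            star, n_replicates=20, seed=14
        )
        assert res.warning is not None
        assert not res.verdict
        np.testing.assert_allclose(res.samples, res.empirical_statistic)

    def test_swap_chain_mixes(self):
        # burn-in adequacy: Q along a long swap chain decorrelates
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        res = degree_preserved_modularity_null(
            g, n_replicates=400, seed=15
        )
        qs = res.samples
        lag1 = np.corrcoef(qs[:-1], qs[1:])[0, 1]
        assert abs(lag1) < 0.2  # replicates are effectively independent


class TestKeystones:
    def _table_for(self, nodes, seed=0):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(6, len(nodes))),
            columns=list(nodes),
        )
        return AbundanceTable(counts)

    def test_star_betweenness(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        table = self._table_for(g.nodes)
        summary = keystone_summary(g, table, n_permutations=99, seed=1)
        rec = summary.records
        assert rec.loc["t0", "betweenness"] == pytest.approx(10.0)  # C(5,2)
        leaves = rec.drop("t0")
        np.testing.assert_allclose(leaves["betweenness"], 0.0)

    def test_complete_graph_zero_betweenness(self):
        g = nx.relabel_nodes(
            nx.complete_graph(5), {i: f"t{i}" for i in range(5)}
        )
        table = self._table_for(g.nodes)
        summary = keystone_summary(g, table, n_permutations=99, seed=2)
        np.testing.assert_allclose(summary.records["betweenness"], 0.0)

    def test_missing_taxon_named(self):
        g = nx.Graph([("a", "b")])
        table = self._table_for(["a"])
        with pytest.raises(ValueError, match="'b'"):
            keystone_summary(g, table)

    def test_permutation_p_uniform_under_null(self):
        # abundances independent of topology: permutation p ~ uniform
        g = sample_gnm(25, 40, seed=3)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        pvals = []
        for i in range(200):
            table = self._table_for(g.nodes, seed=100 + i)
            s = keystone_summary(g, table, n_permutations=199, seed=i)
            pvals.append(s.spearman_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01 or np.mean(np.array(pvals) <= 0.05) <= 0.08

    def test_abundance_column_bounds(self, grouped_table):
        g = nx.Graph()
        g.add_nodes_from(grouped_table.taxon_ids[:4])
        g.add_edges_from(
            combinations(grouped_table.taxon_ids[:3], 2)
        )
        s = keystone_summary(g, grouped_table, n_permutations=99, seed=4)
        assert ((s.records["mean_relative_abundance"] >= 0)
                & (s.records["mean_relative_abundance"] <= 1)).all()
        assert (s.records["degree"] >= 0).all()


class TestMeanDegree:
    def test_identity(self):
        for seed in range(5):
            g = sample_gnm(17, 23, seed=seed)
            assert mean_degree(g) == pytest.approx(2 * 23 / 17)
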