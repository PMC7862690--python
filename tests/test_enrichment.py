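"""RWR and NetPEA against independent oracles.

The iterative random walk is checked against a direct linear solve built
here from scratch; NetPEA permutation z-scores are checked against
exhaustive enumeration of all same-size gene sets on networks small
enough to enumerate.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathdsp import (
    GeneSetCollection,
    NetPEA,
    netpea_enrich,
    pathway_closeness,
    random_walk_with_restart,
)


def _solve_oracle(network, seeds, c):
    """Independent closed-form RWR: p = solve(I - (1-c)M, c e)."""
    nodes = list(network.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    col = A.sum(axis=0)
    dangling = col == 0
    W = np.divide(A, col, out=np.zeros_like(A), where=~dangling)
    e = np.zeros(n)
    idx = [nodes.index(s) for s in seeds if s in nodes]
    e[idx] = 1.0 / len(idx)
    M = W + np.outer(e, dangling.astype(float))
    return nodes, np.linalg.solve(np.eye(n) - (1 - c) * M, c * e)


def _random_graph(seed, max_nodes=20):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.6)), seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
    for a, b in g.edges:
        g[a][b]["weight"] = float(rng.uniform(0.1, 1.0))
    return g, rng


class TestRandomWalkWithRestart:
    @pytest.mark.parametrize("seed", range(50))
    def test_iterative_matches_linear_solve(self, seed):
        g, rng = _random_graph(seed)
        nodes = list(g.nodes)
        seeds = list(rng.choice(nodes, size=int(rng.integers(1, 4)), replace=False))
        c = float(rng.uniform(0.1, 0.9))
        nsv = random_walk_with_restart(g, seeds, restart_prob=c, tol=1e-12,
                                       max_iter=100000, method="iterative")
        oracle_nodes, p = _solve_oracle(g, seeds, c)
        got = nsv.scores[oracle_nodes].to_numpy()
        assert np.max(np.abs(got - p)) < 1e-8
        assert nsv.scores.sum() == pytest.approx(1.0, abs=1e-8)
        assert (nsv.scores >= 0).all()

    def test_restart_prob_one_returns_seed_distribution(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        nsv = random_walk_with_restart(g, ["A", "B"], restart_prob=1.0)
        assert nsv.scores.to_dict() == {"A": 0.5, "B": 0.5, "C": 0.0}

    def test_single_node_network(self):
        g = nx.Graph()
        g.add_node("A")
        nsv = random_walk_with_restart(g, ["A"], restart_prob=0.5)
        assert nsv.scores["A"] == pytest.approx(1.0)

    def test_path_graph_hand_values(self):
        # A-B-C, seeds={A}, c=0.5: closed-form solution of the 3x3 system
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        nsv = random_walk_with_restart(g, ["A"], restart_prob=0.5)
        assert nsv.scores["A"] == pytest.approx(0.5833, abs=1e-4)
        assert nsv.scores["B"] == pytest.approx(0.3333, abs=1e-4)
        assert nsv.scores["C"] == pytest.approx(0.0833, abs=1e-4)

    def test_monotone_decay_along_path(self):
        g = nx.path_graph(8)
        nx.set_edge_attributes(g, 1.0, "weight")
        nsv = random_walk_with_restart(g, [0], restart_prob=0.5)
        vals = nsv.scores[list(range(8))].to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)

    def test_unmapped_seeds_dropped_and_reported(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        nsv = random_walk_with_restart(g, ["A", "ZZZ"], restart_prob=0.5)
        assert nsv.seeds_used == ["A"] and nsv.seeds_dropped == ["ZZZ"]

    def test_no_mapped_seed_raises(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        with pytest.raises(ValueError, match="no seed"):
            random_walk_with_restart(g, ["X"], restart_prob=0.5)

    @pytest.mark.parametrize("c", [0.0, 1.5, -0.2])
    def test_restart_prob_validated(self, c):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        with pytest.raises(ValueError, match="restart_prob"):
            random_walk_with_restart(g, ["A"], restart_prob=c)


class TestPathwayCloseness:
    def _path_nsv(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        return random_walk_with_restart(g, ["A"], restart_prob=0.5)

    def test_whole_network_pathway_gives_uniform_mean(self):
        nsv = self._path_nsv()
        assert pathway_closeness(nsv, ["A", "B", "C"]) == pytest.approx(1 / 3)

    def test_singleton_pathway_equals_node_score(self):
        nsv = self._path_nsv()
        assert pathway_closeness(nsv, ["A"]) == pytest.approx(0.5833, abs=1e-4)

    def test_unit_weights_identical_to_unweighted(self):
        nsv = self._path_nsv()
        w = {"A": 1.0, "B": 1.0, "C": 1.0}
        assert pathway_closeness(nsv, ["A", "C"], w) == pathway_closeness(nsv, ["A", "C"])

    def test_disjoint_pathway_returns_nan(self):
        nsv = self._path_nsv()
        with pytest.warns(UserWarning, match="closeness is NaN"):
            assert np.isnan(pathway_closeness(nsv, ["X", "Y"]))

    def test_weights_scale_the_mean(self):
        nsv = self._path_nsv()
        doubled = pathway_closeness(nsv, ["A"], {"A": 2.0})
        assert doubled == pytest.approx(2 * pathway_closeness(nsv, ["A"]))


def _enumeration_oracle(values, k):
    """Exhaustive null of mean(values over S) across all size-k subsets."""
    means = [np.mean([values[i] for i in s])
             for s in itertools.combinations(range(len(values)), k)]
    return float(np.mean(means)), float(np.std(means))


class TestNetPEA:
    def _toy(self):
        g = nx.Graph()
        for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E")]:
            g.add_edge(a, b, weight=1.0)
        pathways = GeneSetCollection(
            sets={f"P_{n}": [n] for n in "ABCDE"},
            descriptions={},
        )
        return g, pathways

    def test_sampled_z_matches_enumeration_on_singletons(self):
        g, pathways = self._toy()
        em = netpea_enrich(g, {"cell1": {"A"}}, pathways, n_perm=1000, rng_seed=3)
        nsv = random_walk_with_restart(g, {"A"})
        values = nsv.scores[list(g.nodes)].to_numpy()
        mu, sigma = _enumeration_oracle(values, 1)
        for name in pathways.names():
            node = name.split("_")[1]
            z_exact = (nsv.scores[node] - mu) / sigma
            z_got = em.values.loc["cell1", name]
            se = np.sqrt((1 + z_exact**2 / 2) / 1000)
            assert abs(z_got - z_exact) < 3 * se, name

    def test_unit_weights_bit_identical_to_unweighted(self):
        g, pathways = self._toy()
        seeds = {"c1": {"A"}, "c2": {"B", "C"}}
        plain = netpea_enrich(g, seeds, pathways, n_perm=200, rng_seed=9)
        ones = {c: {n: 1.0 for n in g.nodes} for c in seeds}
        weighted = netpea_enrich(g, seeds, pathways, n_perm=200, rng_seed=9,
                                 gene_weights_per_entity=ones)
        assert plain.values.equals(weighted.values)

    def test_fixed_seed_is_reproducible(self):
        g, pathways = self._toy()
        a = netpea_enrich(g, {"c": {"A"}}, pathways, n_perm=100, rng_seed=5)
        b = netpea_enrich(g, {"c": {"A"}}, pathways, n_perm=100, rng_seed=5)
        assert a.values.equals(b.values)

    def test_empty_seed_entity_gets_zero_row(self):
        g, pathways = self._toy()
        em = netpea_enrich(g, {"good": {"A"}, "empty": set()}, pathways,
                           n_perm=100, rng_seed=1)
        assert (em.values.loc["empty"] == 0).all()
        assert not (em.values.loc["good"] == 0).all()

    def test_output_shape_entities_by_pathways(self, small_fixture):
        fx = small_fixture
        seeds = {c: {g for cc, g in fx.omics.mutations if cc == c}
                 for c in fx.omics.expression.index}
        em = netpea_enrich(fx.network, seeds, fx.gene_sets, n_perm=50, rng_seed=2)
        assert em.values.shape == (len(seeds), len(fx.gene_sets))
        assert np.isfinite(em.values.to_numpy()).all()

    def test_score_at_null_mean_gives_zero_z(self):
        # a pathway covering the entire node universe scores exactly the
        # null mean for its size (every size-n subset is the whole set)
        g, _ = self._toy()
        whole = GeneSetCollection(sets={"ALL": list(g.nodes)}, descriptions={})
        with pytest.warns(UserWarning, match="zero variance"):
            em = netpea_enrich(g, {"c": {"A"}}, whole, n_perm=100, rng_seed=0)
        assert em.values.loc["c", "ALL"] == 0.0

    def test_requires_fit_before_transform(self):
        with pytest.raises(RuntimeError, match="fit"):
            NetPEA().transform({"c": {"A"}})
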