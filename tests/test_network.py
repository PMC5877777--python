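import math

import numpy as np
import pytest

from allonet.correlation import CorrelationMatrix
from allonet.network import (
    PathResult,
    ResidueGraph,
    allosteric_pathways,
    build_weighted_network,
    contact_frequencies,
    shortest_path,
)
from allonet.regions import RegionSet
from allonet.structure_io import Residue, Trajectory
from allonet.synthetic import make_random_graph
from oracles import brute_shortest_path


def _residues(n):
    return [Residue("A", i + 1, "ALA") for i in range(n)]


class TestContactFrequencies:
    def test_fixed_contact_has_frequency_one(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 4.0
        f = contact_frequencies(Trajectory(frames, _residues(2)), cutoff=5.7)
        assert f[0, 1] == 1.0

    def test_distant_pair_has_frequency_zero(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 20.0
        f = contact_frequencies(Trajectory(frames, _residues(2)), cutoff=5.7)
        assert f[0, 1] == 0.0

    def test_three_of_six_frames_gives_half(self):
        frames = np.zeros((6, 2, 3))
        frames[:, 1, 0] = [4.0, 4.0, 4.0, 9.0, 9.0, 9.0]
        f = contact_frequencies(Trajectory(frames, _residues(2)), cutoff=5.7)
        assert f[0, 1] == 0.5

    def test_diagonal_is_one(self):
        frames = np.random.default_rng(0).normal(size=(3, 5, 3))
        f = contact_frequencies(Trajectory(frames, _residues(5)), cutoff=5.7)
        np.testing.assert_array_equal(np.diag(f), 1.0)


def _net(corr, freq, **kw):
    n = corr.shape[0]
    return build_weighted_network(
        CorrelationMatrix(corr, _residues(n)), freq, **kw)


class TestBuildWeightedNetwork:
    def _two_node(self, c, f):
        corr = np.array([[1.0, c], [c, 1.0]])
        freq = np.array([[1.0, f], [f, 1.0]])
        return _net(corr, freq)

    def test_low_contact_frequency_prunes_edge(self):
        assert self._two_node(0.9, 0.4).n_edges == 0

    def test_boundary_frequency_half_retains_edge(self):
        assert self._two_node(0.9, 0.5).n_edges == 1

    def test_neglog_cost_value(self):
        rg = self._two_node(0.9, 1.0)
        assert rg.graph[1][2]["cost"] == pytest.approx(-math.log(0.9), abs=1e-12)

    def test_full_correlation_floored_to_positive_cost(self):
        rg = self._two_node(1.0, 1.0)
        cost = rg.graph[1][2]["cost"]
        assert 0 < cost < 1e-9

    def test_anticorrelation_uses_magnitude(self):
        rg = self._two_node(-0.9, 1.0)
        assert rg.graph[1][2]["cost"] == pytest.approx(-math.log(0.9), abs=1e-12)
        assert rg.graph[1][2]["correlation"] == -0.9

    def test_zero_correlation_edge_dropped(self):
        assert self._two_node(0.0, 1.0).n_edges == 0

    def test_linear_transform(self):
        corr = np.array([[1.0, 0.25], [0.25, 1.0]])
        freq = np.ones((2, 2))
        rg = _net(corr, freq, transform="linear")
        assert rg.graph[1][2]["cost"] == pytest.approx(0.75)

    def test_invariant_under_residue_relabeling(self):
        rng = np.random.default_rng(3)
        n = 6
        corr = rng.uniform(-1, 1, (n, n))
        corr = np.clip((corr + corr.T) / 2, -0.99, 0.99)
        np.fill_diagonal(corr, 1.0)
        freq = (rng.uniform(0, 1, (n, n)) > 0.3).astype(float)
        freq = np.maximum(freq, freq.T)
        np.fill_diagonal(freq, 1.0)
        perm = rng.permutation(n)
        rg = _net(corr, freq)
        rg_p = _net(corr[np.ix_(perm, perm)], freq[np.ix_(perm, perm)])
        # map permuted edges back and compare edge sets with costs
        back = {int(perm[i]) + 1: i + 1 for i in range(n)}
        orig = {(min(a, b), max(a, b)): round(d["cost"], 12)
                for a, b, d in rg.edges()}
        mapped = {}
        for a, b, d in rg_p.edges():
            u, v = back[a], back[b]
            mapped[(min(u, v), max(u, v))] = round(d["cost"], 12)
        assert orig == mapped


class TestShortestPath:
    def _hand_graph(self):
        # A=1 B=2 C=3 D=4; costs AB=1, BC=1, AC=3, CD=1, BD=5
        rg = ResidueGraph.empty(range(1, 5))
        for i, j, c in [(1, 2, 1.0), (2, 3, 1.0), (1, 3, 3.0),
                        (3, 4, 1.0), (2, 4, 5.0)]:
            rg.add_edge(i, j, correlation=math.exp(-c), cost=c, contact_freq=1.0)
        return rg

    def test_source_equals_target(self):
        rg = self._hand_graph()
        p = shortest_path(rg, 2, 2)
        assert p.residues == [2] and p.cost == 0.0

    def test_hand_built_example(self):
        p = shortest_path(self._hand_graph(), 1, 4)
        assert p.residues == [1, 2, 3, 4]
        assert p.cost == pytest.approx(3.0)
        assert p.edge_costs == [1.0, 1.0, 1.0]

    def test_unreachable_target_reports_no_path(self):
        rg = ResidueGraph.empty([1, 2, 3])
        rg.add_edge(1, 2, correlation=0.5, cost=0.7, contact_freq=1.0)
        p = shortest_path(rg, 1, 3)
        assert not p.found and p.residues == []

    def test_tie_break_prefers_fewer_hops_then_lex(self):
        rg = ResidueGraph.empty(range(1, 6))
        # two cost-2 routes 1->4: direct edge of 2 (1 hop) vs 1-2-4 (2 hops)
        rg.add_edge(1, 4, correlation=0.1, cost=2.0, contact_freq=1.0)
        rg.add_edge(1, 2, correlation=0.4, cost=1.0, contact_freq=1.0)
        rg.add_edge(2, 4, correlation=0.4, cost=1.0, contact_freq=1.0)
        assert shortest_path(rg, 1, 4).residues == [1, 4]
        # equal cost and hops: 1-2-5 vs 1-3-5 -> lexicographic 1-2-5
        rg2 = ResidueGraph.empty(range(1, 6))
        for i, j in [(1, 2), (2, 5), (1, 3), (3, 5)]:
            rg2.add_edge(i, j, correlation=0.4, cost=1.0, contact_freq=1.0)
        assert shortest_path(rg2, 1, 5).residues == [1, 2, 5]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        rg = make_random_graph(n, float(rng.uniform(0.2, 0.9)),
                               (0.1, 2.0), seed=seed + 1000)
        source, target = 1, n
        ours = shortest_path(rg, source, target)
        brute = brute_shortest_path(rg.graph, source, target)
        if brute is None:
            assert not ours.found
        else:
            assert ours.found
            assert abs(ours.cost - brute[0]) <= 1e-12
            assert list(brute[2]) == ours.residues

    def test_removing_edge_never_shortens_paths(self):
        for seed in range(10):
            rg = make_random_graph(8, 0.6, (0.1, 1.5), seed=seed)
            if rg.n_edges == 0:
                continue
            before = shortest_path(rg, 1, 8)
            edge = sorted(rg.graph.edges())[0]
            rg.graph.remove_edge(*edge)
            after = shortest_path(rg, 1, 8)
            if before.found and after.found:
                assert after.cost >= before.cost - 1e-12
            elif before.found:
                assert not after.found or after.cost >= before.cost


class TestAllostericPathways:
    def test_target_is_site_gives_trivial_path(self):
        rg = make_random_graph(5, 1.0, (0.5, 0.5), seed=0)
        bundle = allosteric_pathways(rg, 3, RegionSet.from_residues({3}))
        assert bundle.paths[3].residues == [3]
        assert bundle.edge_union == []

    def test_unreachable_targets_leave_union_unchanged(self):
        rg = ResidueGraph.empty(range(1, 6))
        rg.add_edge(1, 2, correlation=0.5, cost=0.7, contact_freq=1.0)
        bundle = allosteric_pathways(rg, 1, RegionSet.from_residues({4, 5}))
        assert all(not p.found for p in bundle.paths.values())
        assert bundle.edge_union == []

    def test_shared_stem_appears_once_in_union(self):
        # stem 1-2-3 then fan-out to region {4,5,6}
        rg = ResidueGraph.empty(range(1, 7))
        for i, j in [(1, 2), (2, 3), (3, 4), (3, 5), (3, 6)]:
            rg.add_edge(i, j, correlation=0.5, cost=1.0, contact_freq=1.0)
        bundle = allosteric_pathways(rg, 1, RegionSet.from_residues({4, 5, 6}))
        assert bundle.edge_union == [(1, 2), (2, 3), (3, 4), (3, 5), (3, 6)]

    def test_empty_target_set(self):
        rg = make_random_graph(4, 1.0, (1, 1), seed=0)
        bundle = allosteric_pathways(rg, 1, RegionSet())
        assert bundle.paths == {} and bundle.edge_union == []


def test_path_result_cost_is_sum_of_edge_costs():
    p = PathResult([1, 2, 3], 1.5, [0.7, 0.8])
    assert p.cost == pytest.approx(sum(p.edge_costs))
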