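import itertools

import networkx as nx
import numpy as np
import pytest

from netprior.network import InteractionNetwork
from netprior.prioritizers import (ConvergenceError, DiffusionConfig,
                                   RandomWalkScorer, diffusion_exact,
                                   interconnectivity_pair,
                                   interconnectivity_score,
                                   neighborhood_score, network_propagation,
                                   random_walk)
from netprior.signature import NodeSignal

from conftest import nx_to_net, random_net


def signal_for(net, weights=None, deg_nodes=()):
    w = np.zeros(net.n_nodes)
    idx = net.index()
    for node, val in (weights or {}).items():
        w[idx[node]] = val
    return NodeSignal(weights=w, deg_nodes=set(deg_nodes), nodes=net.nodes)


# -- independent brute-force oracles ----------------------------------

def brute_neighborhood(net, fc):
    scores = {}
    for i in net.nodes:
        nb = net.neighbors(i)
        second = sum(fc.get(n, 0.0) for n in nb) / len(nb) if nb else 0.0
        scores[i] = 0.5 * fc.get(i, 0.0) + 0.5 * second
    return scores


def brute_interconnectivity(net, degs):
    def icn(i, j):
        di, dj = net.degree(i), net.degree(j)
        if di == 0 or dj == 0:
            return 0.0
        e = 1.0 if net.has_edge(i, j) else 0.0
        shared = len(net.neighbors(i) & net.neighbors(j))
        return (e + shared) / np.sqrt(di * dj)

    return {i: sum(icn(i, d) for d in degs if d != i) for i in net.nodes}


class TestNeighborhood:
    def test_path_example(self, path_net):
        s = signal_for(path_net, {"A": 2.0}, {"A"})
        scores = dict(zip(path_net.nodes, neighborhood_score(path_net, s)))
        assert scores["B"] == pytest.approx(0.5)
        assert scores["A"] == pytest.approx(1.0)

    def test_no_deg_neighborhood_scores_zero(self, six_node_net):
        s = signal_for(six_node_net, {"A": 1.0}, {"A"})
        scores = dict(zip(six_node_net.nodes,
                          neighborhood_score(six_node_net, s)))
        assert scores["F"] == 0.0  # F is two hops from any fold change

    def test_isolated_deg_node(self):
        net = InteractionNetwork(edges=[("A", "B")], nodes=["Z"])
        s = signal_for(net, {"Z": 3.0}, {"Z"})
        scores = dict(zip(net.nodes, neighborhood_score(net, s)))
        assert scores["Z"] == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        net = random_net(15, 0.25, seed)
        rng = np.random.default_rng(seed)
        degs = [n for n in net.nodes if rng.random() < 0.3] or [net.nodes[0]]
        fc = {d: float(rng.uniform(0.5, 3)) for d in degs}
        s = signal_for(net, fc, degs)
        got = neighborhood_score(net, s)
        want = brute_neighborhood(net, fc)
        assert np.allclose(got, [want[n] for n in net.nodes])


class TestInterconnectivity:
    def test_adjacent_pair_with_shared_neighbor(self):
        # i-j adjacent, both degree 2 via a shared neighbor
        net = InteractionNetwork(edges=[("i", "j"), ("i", "s"), ("j", "s")])
        assert interconnectivity_pair(net, "i", "j") == pytest.approx(1.0)

    def test_unrelated_pair_zero(self):
        net = InteractionNetwork(edges=[("i", "a"), ("j", "b")])
        assert interconnectivity_pair(net, "i", "j") == 0.0

    def test_star_center_leaf(self):
        net = InteractionNetwork(edges=[("c", "l"), ("c", "x"), ("c", "y")])
        assert interconnectivity_pair(net, "c", "l") == \
            pytest.approx(1 / np.sqrt(3))

    def test_self_pair_errors(self, path_net):
        with pytest.raises(ValueError):
            interconnectivity_pair(path_net, "A", "A")

    def test_harmonic_normalization(self):
        net = InteractionNetwork(edges=[("c", "l"), ("c", "x"), ("c", "y")])
        got = interconnectivity_score(net, {"l"}, normalization="harmonic")
        scores = dict(zip(net.nodes, got))
        assert scores["c"] == pytest.approx(1 / ((3 + 1) / 2))

    def test_single_deg_sum_is_pair(self, six_node_net):
        net = six_node_net
        got = dict(zip(net.nodes, interconnectivity_score(net, {"C"})))
        for i in net.nodes:
            if i == "C":
                continue
            assert got[i] == pytest.approx(
                interconnectivity_pair(net, i, "C"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        net = random_net(20, 0.2, seed)
        rng = np.random.default_rng(seed)
        degs = {n for n in net.nodes if rng.random() < 0.25} or {net.nodes[0]}
        got = interconnectivity_score(net, degs)
        want = brute_interconnectivity(net, degs)
        assert np.allclose(got, [want[n] for n in net.nodes])

    def test_empty_deg_set_errors(self, path_net):
        with pytest.raises(ValueError):
            interconnectivity_score(path_net, set())


class TestRandomWalk:
    def test_two_seeds_symmetric(self):
        net = InteractionNetwork(edges=[("A", "B")])
        p = random_walk(net, {"A", "B"}, DiffusionConfig(alpha=0.3))
        assert np.allclose(p, [0.5, 0.5], atol=1e-9)

    def test_fixture_matches_exact_solve(self, six_node_net):
        p = random_walk(six_node_net, {"A", "D"},
                        DiffusionConfig(alpha=0.5, tol=1e-9))
        exact = diffusion_exact(six_node_net, {"A", "D"}, 0.5, "random_walk")
        assert np.abs(p - exact).sum() < 1e-6

    def test_restart_dominates_as_alpha_to_one(self, six_node_net):
        p = random_walk(six_node_net, {"A"}, DiffusionConfig(alpha=0.999))
        p0 = np.zeros(6)
        p0[six_node_net.index()["A"]] = 1.0
        assert np.abs(p - p0).sum() < 0.01

    def test_mass_conserved_every_iteration_with_dangling(self):
        net = InteractionNetwork(edges=[("A", "B"), ("B", "C")],
                                 nodes=["iso1", "iso2"])
        sums = []
        scorer = RandomWalkScorer(alpha=0.4).fit(net)
        s = signal_for(net, deg_nodes={"A", "iso1"})
        p = scorer.transform(s, callback=lambda v: sums.append(v.sum()))
        assert all(abs(t - 1.0) < 1e-9 for t in sums)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonconvergence_raises(self, six_node_net):
        with pytest.raises(ConvergenceError, match="residual"):
            random_walk(six_node_net, {"A"},
                        DiffusionConfig(alpha=0.5, tol=1e-12, max_iter=3))


class TestPropagation:
    def test_alpha_to_zero_recovers_prior(self, six_node_net):
        f = network_propagation(six_node_net, {"A"},
                                DiffusionConfig(alpha=1e-4))
        f0 = np.zeros(6)
        f0[six_node_net.index()["A"]] = 1.0
        assert np.abs(f - f0).sum() < 1e-3

    def test_fixture_matches_closed_form(self, six_node_net):
        f = network_propagation(six_node_net, {"A", "D"},
                                DiffusionConfig(alpha=0.5, tol=1e-9))
        exact = diffusion_exact(six_node_net, {"A", "D"}, 0.5, "propagation")
        assert np.abs(f - exact).sum() < 1e-6

    def test_symmetric_seed_pair_equal_scores(self):
        net = InteractionNetwork(edges=[("A", "B")])
        f = network_propagation(net, {"A", "B"})
        assert f[0] == pytest.approx(f[1])

    def test_single_edge_hand_algebra(self):
        """One seed on a single edge at alpha=0.5: solving the 2x2 system
        (I - 0.5 A')F = 0.5 F0 by hand gives F = (2/3, 1/3)."""
        net = InteractionNetwork(edges=[("A", "B")])
        exact = diffusion_exact(net, {"A"}, 0.5, "propagation")
        assert np.allclose(exact, [2 / 3, 1 / 3])
        f = network_propagation(net, {"A"}, DiffusionConfig(tol=1e-10))
        assert np.abs(f - exact).sum() < 1e-8


class TestCrossMethodProperties:
    @pytest.mark.parametrize("method", ["random_walk", "propagation"])
    @pytest.mark.parametrize("seed", range(10))
    def test_iterative_agrees_with_exact_on_random_graphs(self, method, seed):
        net = random_net(20, 0.2, seed)
        rng = np.random.default_rng(seed)
        eligible = [n for n in net.nodes if net.degree(n) > 0]
        degs = set(rng.choice(eligible, size=3, replace=False))
        cfg = DiffusionConfig(alpha=0.5, tol=1e-10)
        if method == "random_walk":
            got = random_walk(net, degs, cfg)
        else:
            got = network_propagation(net, degs, cfg)
        exact = diffusion_exact(net, degs, 0.5, method)
        assert np.abs(got - exact).sum() < 1e-6

    @pytest.mark.parametrize("method", ["random_walk", "propagation"])
    def test_seed_membership_monotone(self, six_node_net, method):
        """Adding a node to the seed set never decreases its own score."""
        fn = random_walk if method == "random_walk" else network_propagation
        idx = six_node_net.index()["F"]
        before = fn(six_node_net, {"A"})[idx]
        after = fn(six_node_net, {"A", "F"})[idx]
        assert after >= before

    def test_component_without_deg_scores_zero_all_methods(self):
        net = InteractionNetwork(
            edges=[("A", "B"), ("B", "C"), ("X", "Y")])
        s = signal_for(net, {"A": 2.0}, {"A"})
        outside = [net.index()["X"], net.index()["Y"]]
        for vec in (neighborhood_score(net, s),
                    interconnectivity_score(net, {"A"}),
                    random_walk(net, {"A"}),
                    network_propagation(net, {"A"})):
            assert np.all(vec[outside] == 0)

    def test_propagation_start_independent(self, six_node_net):
        """The fixed point does not depend on whether iteration starts from
        F0 or from zeros."""
        from netprior.network import build_adjacency, normalize_symmetric
        A = normalize_symmetric(build_adjacency(six_node_net)).matrix
        f0 = np.zeros(6)
        f0[six_node_net.index()["A"]] = 1.0
        for start in (f0.copy(), np.zeros(6)):
            f = start
            for _ in range(10000):
                f_next = 0.5 * (A @ f) + 0.5 * f0
                if np.abs(f_next - f).sum() < 1e-12:
                    break
                f = f_next
            assert np.abs(
                f - diffusion_exact(six_node_net, {"A"}, 0.5, "propagation")
            ).sum() < 1e-9

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            DiffusionConfig(alpha=1.0)
        with pytest.raises(ValueError):
            DiffusionConfig(alpha=0.0)
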