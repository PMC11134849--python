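"""Random-walk-with-restart, empirical filtering, direction networks."""

import numpy as np
import pytest

from egosig.network import RandomEnsemble, laplacian_normalize
from egosig.propagation import (
    DirectionNetwork,
    NullScores,
    RWRVector,
    empirical_filter,
    propagate_direction,
    resolve_dual_membership,
    rwr,
)
from egosig.seeds import SeedLayers
from conftest import make_weighted


def _transition(net):
    import networkx as nx

    A = nx.to_numpy_array(net.graph, nodelist=net.nodes, weight="weight")
    colsum = A.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return A / colsum


class TestRWR:
    def test_zero_damping_returns_restart(self):
        net = laplacian_normalize(make_weighted([("a", "b"), ("b", "c")]))
        restart = np.array([0.2, 0.5, 0.3])
        out = rwr(net, restart, damping=0.0)
        assert np.allclose(out.p, restart)

    def test_single_node(self):
        import networkx as nx
        from egosig.network import WeightedNetwork

        g = nx.Graph()
        g.add_node("x")
        out = rwr(WeightedNetwork(graph=g), np.array([1.0]), 0.85)
        assert out.p.tolist() == [1.0]

    def test_two_node_symmetry(self):
        net = laplacian_normalize(make_weighted([("a", "b")]))
        out = rwr(net, np.array([0.5, 0.5]), damping=0.7)
        assert np.allclose(out.p, [0.5, 0.5], atol=1e-9)

    @pytest.mark.parametrize("damping", [0.0, 0.5, 0.7, 0.85])
    def test_probability_vector_for_all_dampings(self, damping, small_normalized):
        n = len(small_normalized.nodes)
        restart = np.zeros(n)
        restart[:4] = 0.25
        out = rwr(small_normalized, restart, damping)
        assert np.all(out.p >= 0)
        assert out.p.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("damping", [0.5, 0.85])
    def test_matches_direct_linear_solution_on_small_graphs(self, damping):
        # p = (I - d T)^(-1) (1-d) r  is the closed-form fixed point
        nets = [
            make_weighted([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]),
            make_weighted(
                [("a", "b", 0.3), ("b", "c", 1.2), ("c", "a", 0.5),
                 ("c", "d", 0.9), ("d", "e", 0.2), ("e", "f", 1.1)]
            ),
        ]
        rng = np.random.default_rng(0)
        for raw in nets:
            net = laplacian_normalize(raw)
            n = len(net.nodes)
            restart = rng.dirichlet(np.ones(n))
            T = _transition(net)
            direct = np.linalg.solve(
                np.eye(n) - damping * T, (1 - damping) * restart
            )
            out = rwr(net, restart, damping)
            assert np.abs(out.p - direct).max() < 1e-8

    def test_invalid_restart_rejected(self, small_normalized):
        n = len(small_normalized.nodes)
        with pytest.raises(ValueError):
            rwr(small_normalized, np.ones(n), 0.85)  # sums to n, not 1


class TestEmpiricalFilter:
    def _null(self, nodes, scores):
        return NullScores(nodes=nodes, scores=np.asarray(scores, dtype=float))

    def test_score_beating_enough_nulls_retained(self):
        # 951 of 1000 nulls strictly below -> retained at alpha 0.05
        nodes = ["a"]
        nulls = np.concatenate([np.zeros(951), np.full(49, 2.0)])[:, None]
        real = RWRVector(nodes=nodes, p=np.array([1.0]), damping=0.85)
        kept, p = empirical_filter(real, self._null(nodes, nulls), alpha=0.05)
        assert kept == {"a"}
        assert p["a"] == pytest.approx(0.049)

    def test_exactly_950_not_retained(self):
        nodes = ["a"]
        nulls = np.concatenate([np.zeros(950), np.full(50, 2.0)])[:, None]
        real = RWRVector(nodes=nodes, p=np.array([1.0]), damping=0.85)
        kept, _ = empirical_filter(real, self._null(nodes, nulls), alpha=0.05)
        assert kept == set()

    def test_alpha_one_retains_everything(self):
        nodes = ["a", "b"]
        nulls = np.ones((10, 2))
        real = RWRVector(nodes=nodes, p=np.array([1.0, 1.0]), damping=0.85)
        kept, _ = empirical_filter(real, self._null(nodes, nulls), alpha=1.0)
        assert kept == {"a", "b"}

    def test_ties_count_against_retention(self):
        nodes = ["a"]
        nulls = np.full((100, 1), 0.5)
        real = RWRVector(nodes=nodes, p=np.array([0.5]), damping=0.85)
        kept, p = empirical_filter(real, self._null(nodes, nulls), alpha=0.05)
        assert kept == set()
        assert p["a"] == 1.0

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(30)]
        nulls = rng.random((200, 30))
        real = RWRVector(nodes=nodes, p=rng.random(30), damping=0.85)
        null = self._null(nodes, nulls)
        prev: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.5):
            kept, _ = empirical_filter(real, null, alpha)
            assert prev <= kept
            prev = kept


@pytest.fixture(scope="module")
def propagated(small_network, small_fixture, small_normalized):
    from egosig.network import randomize_ensemble

    ens = randomize_ensemble(small_network, 20, small_fixture.annotation, seed=7)
    layers = SeedLayers(
        direction="up",
        tyr_kinases={"P0000": 2.0},
        other_kinases={"P0001": 1.0, "P0002": 3.0},
        substrates={"P0005": 1.5, "P0007": 2.5},
    )
    return propagate_direction(small_normalized, ens, layers)


class TestDirectionNetwork:
    def test_seeds_always_included(self, propagated):
        for seed in ("P0000", "P0001", "P0002", "P0005", "P0007"):
            assert seed in propagated.network.graph

    def test_node_set_within_base_network(self, propagated, small_normalized):
        assert set(propagated.network.nodes) <= set(small_normalized.nodes)

    def test_layer_scores_attached(self, propagated):
        assert set(propagated.layer_scores) == {
            "tyr_kinases", "other_kinases", "substrates"
        }

    def test_pipeline_reproducible_for_fixed_seed(
        self, small_network, small_fixture, small_normalized
    ):
        from egosig.network import randomize_ensemble

        layers = SeedLayers(direction="up", substrates={"P0003": 1.0, "P0009": 2.0})
        outs = []
        for _ in range(2):
            ens = randomize_ensemble(
                small_network, 10, small_fixture.annotation, seed=13
            )
            dn = propagate_direction(small_normalized, ens, layers)
            outs.append(sorted(dn.network.nodes))
        assert outs[0] == outs[1]


class TestDualMembership:
    def _dirnet(self, direction, nodes, seeds, scores):
        net = make_weighted(
            [(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)]
        )
        return DirectionNetwork(
            direction=direction,
            network=net,
            seeds=set(seeds),
            layer_scores={"substrates": scores},
        )

    def test_shared_protein_removed_from_weaker_side(self):
        up = self._dirnet("up", ["X", "A"], [], {"X": 0.30, "A": 0.1})
        down = self._dirnet("down", ["X", "B"], [], {"X": 0.10, "B": 0.1})
        u2, d2 = resolve_dual_membership(up, down)
        assert "X" in u2.network.graph
        assert "X" not in d2.network.graph

    def test_keep_dual_leaves_both(self):
        up = self._dirnet("up", ["X", "A"], [], {"X": 0.30})
        down = self._dirnet("down", ["X", "B"], [], {"X": 0.10})
        u2, d2 = resolve_dual_membership(up, down, keep_dual=True)
        assert "X" in u2.network.graph and "X" in d2.network.graph

    def test_exact_tie_goes_to_up(self):
        up = self._dirnet("up", ["X", "A"], [], {"X": 0.2})
        down = self._dirnet("down", ["X", "B"], [], {"X": 0.2})
        u2, d2 = resolve_dual_membership(up, down)
        assert "X" in u2.network.graph and "X" not in d2.network.graph

    def test_direction_exclusive_seed_never_removed(self):
        up = self._dirnet("up", ["X", "A"], ["X"], {"X": 0.01})
        down = self._dirnet("down", ["X", "B"], [], {"X": 0.99})
        u2, d2 = resolve_dual_membership(up, down)
        assert "X" in u2.network.graph and "X" not in d2.network.graph
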