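"""Ego extraction, z-filtering, re-weighting, decomposition, supernodes."""

import math

import numpy as np
import pytest

from egosig.ego import (
    DecompositionPoint,
    EgoNetwork,
    build_supernode,
    extract_ego,
    functional_distance,
    kde_select,
    node_rwr,
    reweight_ego_edges,
    topological_affinity,
    z_filter,
)
from egosig.network import SemanticProfile, laplacian_normalize
from egosig.propagation import DirectionNetwork, RWRVector
from egosig.ontology import compute_information_content
from conftest import make_weighted


def _dirnet(edges, seeds=()):
    return DirectionNetwork(
        direction="up", network=make_weighted(edges), seeds=set(seeds)
    )


class TestExtractEgo:
    def test_isolated_ego(self):
        import networkx as nx
        from egosig.network import WeightedNetwork

        g = nx.Graph()
        g.add_node("a")
        dn = DirectionNetwork(direction="up", network=WeightedNetwork(graph=g),
                              seeds={"a"})
        assert extract_ego(dn, "a") == {"a"}

    def test_path_graph_two_steps(self):
        dn = _dirnet([("a", "b"), ("b", "c"), ("c", "d")])
        assert extract_ego(dn, "a") == {"a", "b", "c"}

    def test_complete_graph_everything(self):
        nodes = ["a", "b", "c", "d"]
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        dn = _dirnet(edges)
        assert extract_ego(dn, "a") == set(nodes)

    def test_missing_ego_raises(self):
        dn = _dirnet([("a", "b")])
        with pytest.raises(ValueError):
            extract_ego(dn, "zzz")


class TestZFilter:
    def _profile(self, mean, std):
        return SemanticProfile(mean={"ego": mean}, std={"ego": std})

    def _ann(self, sims):
        class Fake:
            def simgic(self, a, b):
                return sims[b]
        return Fake()

    def test_similarity_at_mean_excluded(self):
        ann = self._ann({"j": 0.5})
        kept = z_filter({"j"}, "ego", self._profile(0.5, 0.1), ann)
        assert kept == {"ego"}

    def test_two_sigma_above_mean_kept(self):
        ann = self._ann({"j": 0.7})  # z = 2
        kept = z_filter({"j"}, "ego", self._profile(0.5, 0.1), ann)
        assert kept == {"ego", "j"}

    def test_cutoff_matches_one_tailed_95_quantile(self):
        from scipy.stats import norm
        from egosig.ego import Z_CUTOFF

        assert round(float(norm.ppf(0.95)), 2) == Z_CUTOFF

    def test_zero_variance_degenerates_to_mean_comparison(self):
        ann = self._ann({"hi": 0.8, "lo": 0.2})
        with pytest.warns(UserWarning, match="variance"):
            kept = z_filter({"hi", "lo"}, "ego", self._profile(0.5, 0.0), ann)
        assert kept == {"ego", "hi"}


class TestReweight:
    @pytest.fixture()
    def annotated_path(self):
        # ego-a-b path plus ego-c: distinct term sets with controlled overlap
        parents = {t: set() for t in ("t1", "t2", "t3", "t4")}
        raw = {
            "ego": {"t1", "t2"},
            "a": {"t1", "t3"},
            "b": {"t2", "t3"},
            "c": {"t4"},
        }
        return compute_information_content(raw, parents)

    def test_ego_incident_edges_use_pair_simgic(self, annotated_path):
        dn = _dirnet([("ego", "a"), ("a", "b")])
        en = reweight_ego_edges(dn, "ego", {"ego", "a", "b"}, annotated_path)
        d = en.network.raw_degree
        raw = en.network.weight("ego", "a") * math.sqrt(d["ego"] * d["a"])
        assert raw == pytest.approx(annotated_path.simgic("ego", "a"))

    def test_non_ego_edges_average_ego_similarities(self, annotated_path):
        dn = _dirnet([("ego", "a"), ("ego", "b"), ("a", "b")])
        en = reweight_ego_edges(dn, "ego", {"ego", "a", "b"}, annotated_path)
        d = en.network.raw_degree
        raw = en.network.weight("a", "b") * math.sqrt(d["a"] * d["b"])
        expected = (
            annotated_path.simgic("ego", "a") + annotated_path.simgic("ego", "b")
        ) / 2
        assert raw == pytest.approx(expected)

    def test_orders_classified(self, annotated_path):
        dn = _dirnet([("ego", "a"), ("a", "b")])
        en = reweight_ego_edges(dn, "ego", {"ego", "a", "b"}, annotated_path)
        assert en.first_order == {"a"}
        assert en.second_order == {"b"}


class TestAffinityAndDistance:
    def _vec(self, p):
        return RWRVector(nodes=[f"n{i}" for i in range(len(p))],
                         p=np.asarray(p, dtype=float), damping=0.85)

    def test_identical_vectors_score_1000(self):
        v = self._vec([0.25, 0.75])
        assert topological_affinity(v, v) == pytest.approx(1000.0)

    def test_disjoint_vectors_score_0(self):
        a, b = self._vec([1.0, 0.0]), self._vec([0.0, 1.0])
        assert topological_affinity(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_matches_entropy_based_jsd_oracle(self):
        # brute-force JSD from Shannon entropies: JSD^2 = H(m) - (H(p)+H(q))/2
        p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])

        def H(x):
            x = x[x > 0]
            return -(x * np.log2(x)).sum()

        m = (p + q) / 2
        jsd = math.sqrt(H(m) - (H(p) + H(q)) / 2)
        expected = 1000 * math.log2(2 - jsd)
        got = topological_affinity(self._vec(p), self._vec(q))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_monotone_decreasing_in_jsd(self):
        vals = [1000 * math.log2(2 - j) for j in np.linspace(0, 1, 11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_functional_distance_boundaries(self):
        class Fake:
            def __init__(self, s):
                self.s = s
            def simgic(self, a, b):
                return self.s

        assert functional_distance("e", "j", Fake(0.0)) == pytest.approx(0.0)
        assert functional_distance("e", "j", Fake(1.0)) == pytest.approx(1000.0)
        assert functional_distance("e", "j", Fake(0.5)) == pytest.approx(
            1000 * math.log2(1.5)
        )

    def test_monotone_increasing_in_simgic(self):
        vals = [1000 * math.log2(1 + s) for s in np.linspace(0, 1, 11)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_mismatched_supports_rejected(self):
        a = self._vec([1.0, 0.0])
        b = RWRVector(nodes=["x", "y"], p=np.array([0.5, 0.5]), damping=0.85)
        with pytest.raises(ValueError):
            topological_affinity(a, b)


class TestEgoRWRVectors:
    def test_per_node_vectors_are_probability_vectors(self):
        en = EgoNetwork(
            ego="a",
            network=laplacian_normalize(
                make_weighted([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
            ),
            first_order={"b", "c"},
            second_order={"d"},
        )
        for node in ("a", "b", "c", "d"):
            vec = node_rwr(en, node)
            assert np.all(vec.p >= 0)
            assert vec.p.sum() == pytest.approx(1.0, abs=1e-9)


class TestKdeSelect:
    def _points(self, coords):
        return [
            DecompositionPoint(node=f"n{i}", topo=t, func=f)
            for i, (t, f) in enumerate(coords)
        ]

    def _cloud(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2)) * 1000
        return self._points(pts.tolist())

    def test_selection_shrinks_as_threshold_rises(self):
        pts = self._cloud()
        prev = None
        for thr in (0.80, 0.85, 0.90, 0.95):
            sel = kde_select(pts, thr)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_dominating_point_attains_max_cdf(self):
        pts = self._points(
            [(100, 100), (200, 300), (400, 200), (300, 400), (950, 950)]
        )
        kde_select(pts, 0.5)
        best = max(pts, key=lambda p: p.cdf)
        assert best.node == "n4"

    def test_degenerate_cloud_selects_all_with_warning(self):
        pts = self._points([(500, 500), (500, 500)])
        with pytest.warns(UserWarning, match="degenerate"):
            sel = kde_select(pts, 0.85)
        assert sel == {"n0", "n1"}

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            kde_select(self._cloud(), 1.0)


class TestBuildSupernode:
    def _small_egonet(self, n_neighbors):
        edges = [("ego", f"x{i}") for i in range(n_neighbors)]
        return EgoNetwork(
            ego="ego",
            network=laplacian_normalize(make_weighted(edges)),
            first_order={f"x{i}" for i in range(n_neighbors)},
            second_order=set(),
        )

    def test_small_ego_network_kept_whole(self, small_fixture):
        en = self._small_egonet(3)
        sn, pts = build_supernode(en, small_fixture.annotation)
        assert sn.members == en.members
        assert pts == []

    def test_ego_always_member(self, small_fixture):
        en = self._small_egonet(2)
        sn, _ = build_supernode(en, small_fixture.annotation)
        assert "ego" in sn.members
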