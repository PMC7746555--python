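"""Graph-metric correctness against closed forms and brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from covnet import metrics as gm
from conftest import adjacency, ring_lattice


def random_adjacency(n, p, seed):
    return oracles.random_graph(n, p, np.random.default_rng(seed))


class TestClosedForms:
    def test_triangle(self, k3):
        assert gm.clustering_coefficient(k3) == 1.0
        assert gm.characteristic_path_length(k3) == 1.0
        assert gm.global_efficiency(k3) == 1.0
        assert gm.transitivity(k3) == 1.0

    def test_path_graph(self, p3):
        assert np.all(gm.nodal_clustering(p3) == 0)
        assert gm.characteristic_path_length(p3) == pytest.approx(4 / 3)
        assert gm.global_efficiency(p3) == pytest.approx(5 / 6)
        assert np.allclose(gm.betweenness(p3), [0, 1, 0])

    def test_star(self, star4):
        bc = gm.betweenness(star4)
        assert bc[0] == 3.0 and np.all(bc[1:] == 0)
        assert gm.local_efficiency(star4) == 0.0
        assert gm.transitivity(star4) == 0.0

    def test_complete_k4_local_efficiency(self, k4):
        assert gm.local_efficiency(k4) == 1.0

    def test_two_disconnected_edges_efficiency(self):
        a = adjacency([(0, 1), (2, 3)], 4)
        assert gm.global_efficiency(a) == pytest.approx(2 / 6)


class TestModularity:
    def test_two_triangles_exhaustive(self, two_triangles):
        q, membership = gm.modularity(two_triangles, seed=0)
        q_best, p_best = oracles.best_modularity(two_triangles)
        assert q == pytest.approx(0.5) == pytest.approx(q_best)
        # the two triangles are the modules
        assert membership[0] == membership[1] == membership[2]
        assert membership[3] == membership[4] == membership[5]
        assert membership[0] != membership[3]

    def test_complete_graph_single_module(self, k5):
        q, membership = gm.modularity(k5, seed=0)
        q_best, _ = oracles.best_modularity(k5)
        assert q_best == pytest.approx(0.0)
        assert q == pytest.approx(0.0)
        assert len(set(membership)) == 1

    def test_seeded_determinism(self):
        a = random_adjacency(30, 0.2, seed=5)
        q1, m1 = gm.modularity(a, seed=11, restarts=3)
        q2, m2 = gm.modularity(a, seed=11, restarts=3)
        assert q1 == q2 and np.array_equal(m1, m2)

    def test_restarts_never_worse(self):
        a = random_adjacency(40, 0.1, seed=2)
        q1, _ = gm.modularity(a, seed=0, restarts=1)
        q5, _ = gm.modularity(a, seed=0, restarts=5)
        assert q5 >= q1

    def test_no_edges_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            gm.modularity(np.zeros((4, 4), dtype=np.uint8))


@pytest.mark.parametrize("seed", range(10))
def test_metrics_match_brute_force_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    a = oracles.random_graph(n, rng.uniform(0.25, 0.7), rng)
    assert np.allclose(gm.nodal_clustering(a), oracles.clustering_nodal(a), atol=1e-10)
    assert np.allclose(gm.distance_matrix(a), oracles.floyd_warshall(a))
    assert gm.global_efficiency(a) == pytest.approx(oracles.global_efficiency(a))
    assert np.allclose(
        gm.nodal_local_efficiency(a), oracles.local_efficiency_nodal(a), atol=1e-10
    )
    if a.sum() > 0:
        assert gm.characteristic_path_length(a) == pytest.approx(
            oracles.characteristic_path_length(a)
        )
    assert gm.transitivity(a) == pytest.approx(oracles.transitivity(a))
    assert np.allclose(gm.betweenness(a), oracles.betweenness(a), atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.permutations(list(range(8))))
def test_isomorphism_invariance(seed, perm):
    """Relabelling the nodes permutes nodal metrics and leaves global ones."""
    a = random_adjacency(8, 0.4, seed)
    p = np.array(perm)
    b = a[np.ix_(p, p)]
    assert gm.clustering_coefficient(a) == pytest.approx(gm.clustering_coefficient(b))
    assert gm.transitivity(a) == pytest.approx(gm.transitivity(b))
    assert np.allclose(gm.betweenness(a)[p], gm.betweenness(b), atol=1e-10)
    assert np.allclose(gm.nodal_clustering(a)[p], gm.nodal_clustering(b))


class TestRandomEnsemble:
    def test_degree_sequence_preserved(self):
        a = random_adjacency(30, 0.25, seed=3)
        deg = gm.degrees(a)
        rng = np.random.default_rng(0)
        for _ in range(5):
            rewired, successes = gm._edge_swap(a, 10 * int(a.sum() // 2), rng)
            assert successes > 0
            assert np.array_equal(gm.degrees(rewired), deg)
            assert np.array_equal(rewired, rewired.T)
            assert not np.diag(rewired).any()

    def test_rigid_triangle_unchanged_with_warning(self, k3):
        with pytest.warns(UserWarning, match="no admissible"):
            ens = gm.match_random_ensemble(k3, n_random=3, seed=0)
        assert np.allclose(ens.cp_rand, 1.0)
        assert np.allclose(ens.lp_rand, 1.0)

    def test_self_normalization(self, k3):
        with pytest.warns(UserWarning):
            ens = gm.match_random_ensemble(k3, n_random=3, seed=0)
        sw = gm.small_world(k3, ens)
        assert sw.gamma == sw.lam == sw.sigma == 1.0

    def test_ring_lattice_is_more_clustered_than_random(self):
        a = ring_lattice(20, 4)
        ens = gm.match_random_ensemble(a, n_random=30, seed=1)
        sw = gm.small_world(a, ens)
        assert sw.gamma > 1.0
        assert sw.lam >= 1.0

    def test_ensemble_determinism(self):
        a = random_adjacency(25, 0.3, seed=9)
        e1 = gm.match_random_ensemble(a, n_random=10, seed=4)
        e2 = gm.match_random_ensemble(a, n_random=10, seed=4)
        assert np.array_equal(e1.cp_rand, e2.cp_rand)
        assert np.array_equal(e1.lp_rand, e2.lp_rand)

    def test_sigma_identity(self):
        a = ring_lattice(20, 4)
        ens = gm.match_random_ensemble(a, n_random=10, seed=0)
        sw = gm.small_world(a, ens)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam, abs=1e-12)


class TestHubs:
    def test_star_center_is_unique_hub(self):
        n = 10
        star = adjacency([(0, i) for i in range(1, n)], n)
        bc = gm.betweenness(star)
        hubs = gm.detect_hubs(bc)
        assert hubs.regions == ["node_0"]

    def test_regular_graph_no_hubs(self, k5):
        hubs = gm.detect_hubs(gm.betweenness(k5))
        assert hubs.regions == [] and hubs.sd == 0

    def test_p3_middle_below_threshold(self, p3):
        # betweenness {0, 1, 0}: mean 1/3, population SD 0.4714 -> cut 1.0404
        hubs = gm.detect_hubs(gm.betweenness(p3))
        assert hubs.regions == []


class TestNodalBundle:
    def test_normalized_vectors_have_unit_mean(self):
        a = random_adjacency(20, 0.3, seed=6)
        nm = gm.nodal_metrics(a)
        for name in gm.NODAL_METRICS:
            if nm[name].mean() != 0:
                assert nm[f"{name}_normalized"].mean() == pytest.approx(1.0)

    def test_degrees_sum_to_twice_edges(self):
        a = random_adjacency(20, 0.3, seed=8)
        assert gm.degrees(a).sum() == a.sum()


def test_global_metrics_bundle_consistency():
    """The bundle agrees with the individual metric functions."""
    a = random_adjacency(30, 0.25, seed=12)
    out = gm.global_metrics(
        a, which=gm.GLOBAL_METRICS, seed=3, n_random=10, rewires_per_edge=5
    )
    assert out["clustering_coefficient"] == pytest.approx(gm.clustering_coefficient(a))
    assert out["characteristic_path_length"] == pytest.approx(
        gm.characteristic_path_length(a)
    )
    assert out["global_efficiency"] == pytest.approx(gm.global_efficiency(a))
    assert out["transitivity"] == pytest.approx(gm.transitivity(a))
    assert out["sigma"] == pytest.approx(out["gamma"] / out["lambda"], abs=1e-12)
    ens = gm.match_random_ensemble(a, n_random=10, rewires_per_edge=5, seed=3)
    assert out["gamma"] == pytest.approx(gm.clustering_coefficient(a) / ens.mean_cp)


def test_efficiency_lp_inequality():
    """Harmonic-vs-arithmetic mean: Eglob >= 1/Lp on connected graphs."""
    for seed in range(5):
        a = random_adjacency(15, 0.4, seed)
        if not gm.is_connected(a):
            continue
        assert gm.global_efficiency(a) >= 1.0 / gm.characteristic_path_length(a) - 1e-12
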