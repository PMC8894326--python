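"""The 27-measure registry: definitions, conventions, degenerate inputs, oracles."""

import networkx as nx
import numpy as np
import pytest

import parcstab as ps
from parcstab.connectome import AdjacencyMatrix
from parcstab.graph_metrics import REGISTRY, UndefinedMetricError


def adj(values, mode="weighted", tau=0.1):
    return AdjacencyMatrix(np.asarray(values, float), mode, tau)


def k4(mode="weighted"):
    a = np.ones((4, 4)) - np.eye(4)
    return adj(a, mode)


def random_adjacency(rng, n=8, density=0.4, weighted=True):
    a = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    w = rng.uniform(0.2, 1.0, len(iu[0])) if weighted else np.ones(len(iu[0]))
    a[iu] = np.where(mask, w, 0.0)
    return a + a.T


class TestRegistry:
    def test_27_measures(self):
        assert len(ps.list_metrics()) == 27

    def test_8_global_measures(self):
        globals_ = {n for n, s in REGISTRY.items() if s.level == "global"}
        assert globals_ == {"assortativity", "characteristic path length",
                           "community louvain", "density", "global efficiency",
                           "modularity louvain", "modularity finetune",
                           "transitivity"}

    def test_binary_only_measures(self):
        binary = {n for n, s in REGISTRY.items() if s.matrix_domain == "binary"}
        assert binary == {"subgraph centrality", "flow coefficient",
                          "k-coreness centrality"}

    def test_eight_measure_classes(self):
        assert len({s.metric_class for s in REGISTRY.values()}) == 8


class TestKnownValues:
    def test_density_of_k4(self):
        assert ps.compute_metric("density", k4()).value == pytest.approx(1.0)

    def test_transitivity_of_triangle(self):
        tri = adj(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        assert ps.compute_metric("transitivity", tri).value == pytest.approx(1.0)

    def test_characteristic_path_length_of_path3(self):
        # shortest paths (1, 1, 2) → mean over ordered pairs = 4/3
        p3 = adj(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
        value = ps.compute_metric("characteristic path length", p3).value
        assert value == pytest.approx(4 / 3)

    def test_degree_of_star(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        value = ps.compute_metric("degree", adj(star)).value
        assert np.array_equal(value, [4, 1, 1, 1, 1])

    def test_strength_sums_weights(self):
        a = np.array([[0, 0.5, 0.2], [0.5, 0, 0], [0.2, 0, 0]])
        assert np.allclose(ps.compute_metric("strength", adj(a)).value,
                           [0.7, 0.5, 0.2])

    def test_flow_coefficient_complements_clustering(self):
        # star centre: no neighbour pair connected → flow 1; triangle → flow 0
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        fc = ps.compute_metric("flow coefficient", adj(star, "binary")).value
        assert fc[0] == pytest.approx(1.0) and np.all(fc[1:] == 0)
        tri = adj(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), "binary")
        assert np.allclose(ps.compute_metric("flow coefficient", tri).value, 0)

    def test_get_components_sizes(self):
        two = np.zeros((5, 5))
        two[0, 1] = two[1, 0] = 1.0
        two[2, 3] = two[3, 2] = two[3, 4] = two[4, 3] = 1.0
        value = ps.compute_metric("get components", adj(two)).value
        assert np.array_equal(value, [2, 2, 3, 3, 3])


class TestDegreeDensityConservation:
    def test_degree_sum_equals_twice_edges(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = adj(random_adjacency(rng))
            deg = ps.compute_metric("degree", a).value
            assert deg.sum() == 2 * a.n_edges
            dens = ps.compute_metric("density", a).value
            n = a.n_nodes
            assert dens == pytest.approx(2 * a.n_edges / (n * (n - 1)))


class TestComputeAll:
    def test_all_27_succeed_on_well_formed_graph(self):
        # connected, non-regular, weighted: every measure is defined
        rng = np.random.default_rng(2)
        w = random_adjacency(rng, n=10, density=0.5)
        w[0, 1] = w[1, 0] = 0.9  # ensure connectivity of node 0
        aw, ab = adj(w), adj((w != 0).astype(float), "binary")
        res, errors = ps.compute_all(aw, ab, rng=np.random.default_rng(0))
        assert len(res) == 27 and not errors

    def test_edgeless_graph_policy(self):
        z = np.zeros((5, 5))
        res, errors = ps.compute_all(adj(z), adj(z, "binary"),
                                     rng=np.random.default_rng(0))
        assert "characteristic path length" in errors
        assert np.all(res["degree"].value == 0)

    def test_stochastic_measures_reproducible(self):
        rng = np.random.default_rng(11)
        a = adj(random_adjacency(rng, n=12, density=0.5))
        for name in ("modularity louvain", "modularity finetune",
                     "community louvain", "core periphery"):
            r1 = ps.compute_metric(name, a, rng=np.random.default_rng(5))
            r2 = ps.compute_metric(name, a, rng=np.random.default_rng(5))
            assert np.array_equal(np.atleast_1d(r1.value), np.atleast_1d(r2.value))

    def test_binary_metric_requires_binary_matrix(self):
        with pytest.raises(ValueError):
            ps.compute_metric("subgraph centrality", k4("weighted"))


DETERMINISTIC_LOCAL = [
    "bonacich centrality", "betweenness centrality", "eigenvector centrality",
    "shortcuts centrality", "pagerank centrality", "closeness centrality",
    "katz centrality", "degree", "strength", "clustering coefficient",
    "local efficiency", "get components", "topological overlap",
    "matching index", "flow coefficient", "k-coreness centrality",
    "subgraph centrality",
]


class TestPermutationEquivariance:
    @pytest.mark.parametrize("name", DETERMINISTIC_LOCAL)
    def test_local_vectors_permute_with_nodes(self, name):
        rng = np.random.default_rng(8)
        w = random_adjacency(rng, n=9, density=0.5)
        mode = "binary" if name in ps.BINARY_MEASURES else "weighted"
        if mode == "binary":
            w = (w != 0).astype(float)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        v = ps.compute_metric(name, adj(w, mode)).value
        vp = ps.compute_metric(name, adj(wp, mode)).value
        assert np.allclose(vp, v[perm], atol=1e-8)

    @pytest.mark.parametrize("name", ["density", "characteristic path length",
                                      "global efficiency", "transitivity",
                                      "assortativity"])
    def test_globals_invariant_under_permutation(self, name):
        rng = np.random.default_rng(9)
        w = random_adjacency(rng, n=9, density=0.6)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        assert ps.compute_metric(name, adj(w)).value == pytest.approx(
            ps.compute_metric(name, adj(wp)).value)


class TestDistanceOracle:
    def test_binary_path_ends(self):
        p3 = adj(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
        assert ps.shortest_path_oracle(p3, 0)[2] == pytest.approx(2.0)

    def test_half_weight_edge_length_two(self):
        a = adj(np.array([[0, 0.5], [0.5, 0]]))
        assert ps.shortest_path_oracle(a, 0)[1] == pytest.approx(2.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ps.shortest_path_oracle(np.array([[0, -1.0], [-1.0, 0]]), 0)

    def test_distance_measures_match_oracle_on_small_graphs(self):
        """CPL / closeness / efficiency recomputed from oracle distances."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            w = random_adjacency(rng, n=rng.integers(4, 9), density=0.45)
            if not (w != 0).any():
                continue
            n = len(w)
            d = np.array([ps.shortest_path_oracle(w, s) for s in range(n)])
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(d) & off

            if finite.any():
                cpl = ps.compute_metric("characteristic path length", adj(w)).value
                assert cpl == pytest.approx(d[finite].mean())

            eff = ps.compute_metric("global efficiency", adj(w)).value
            inv = np.where(finite, 1.0 / np.where(d == 0, 1, d), 0.0)
            assert eff == pytest.approx(inv.sum() / (n * (n - 1)))

            clo = ps.compute_metric("closeness centrality", adj(w)).value
            for i in range(n):
                reach = finite[i]
                expected = reach.sum() / d[i, reach].sum() if reach.any() else 0.0
                assert clo[i] == pytest.approx(expected)


class TestWeightedBinaryCoincidence:
    @pytest.mark.parametrize("name", ["degree", "clustering coefficient",
                                      "characteristic path length",
                                      "global efficiency", "density",
                                      "betweenness centrality"])
    def test_weighted_equals_binary_on_binary_graph(self, name):
        rng = np.random.default_rng(3)
        a = (random_adjacency(rng, n=8, density=0.5) != 0).astype(float)
        vw = ps.compute_metric(name, adj(a, "weighted")).value
        vb = ps.compute_metric(name, adj(a, "binary")).value
        assert np.allclose(np.atleast_1d(vw), np.atleast_1d(vb))


def test_modularity_prefers_true_communities():
    # two K4 cliques joined by one bridge vs. the same graph's random split
    w = np.zeros((8, 8))
    w[:4, :4] = 1.0
    w[4:, 4:] = 1.0
    np.fill_diagonal(w, 0.0)
    w[3, 4] = w[4, 3] = 1.0
    q = ps.compute_metric("modularity louvain", adj(w),
                          rng=np.random.default_rng(0)).value
    g = nx.from_numpy_array(w)
    q_random = nx.community.modularity(g, [{0, 2, 4, 6}, {1, 3, 5, 7}])
    assert q >= q_random


def test_undefined_metric_is_an_error_not_zero():
    z = np.zeros((4, 4))
    with pytest.raises(UndefinedMetricError):
        ps.compute_metric("characteristic path length", adj(z))
    with pytest.raises(KeyError):
        ps.compute_metric("nonexistent measure", k4())
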