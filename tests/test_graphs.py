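"""Graph construction, the Laplacian penalty and the adaptive kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gsreg.graphs import (
    GraphValidationError,
    KernelParams,
    adaptive_gaussian_kernel,
    complete_graph,
    connected_components,
    disjoint_pairs_graph,
    grid_graph,
    gsr_penalty,
    laplacian_from_weights,
    nn_union_graph,
    read_edgelist,
    read_graphml,
    write_edgelist,
    write_graphml,
)


def pairwise_penalty(z, w):
    """Independent oracle: 1/2 sum over ordered pairs of W_ij (z_i - z_j)^2."""
    z = np.atleast_2d(z)
    total = 0.0
    for row in z:
        s = 0.0
        for i in range(len(row)):
            for j in range(len(row)):
                s += w[i, j] * (row[i] - row[j]) ** 2
        total += 0.5 * s
    return total / z.shape[0]


def kernel_oracle(x, k, floor=1e-8):
    """Scalar-loop oracle for the adaptive Gaussian kernel."""
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((x[i] - x[j]) ** 2).sum())
    sigma = np.zeros(n)
    for i in range(n):
        others = sorted(d[i, j] for j in range(n) if j != i)
        sigma[i] = max(others[k - 1], floor)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                w[i, j] = 0.5 * np.exp(-d[i, j] ** 2 / (2 * sigma[i] ** 2)) + \
                    0.5 * np.exp(-d[i, j] ** 2 / (2 * sigma[j] ** 2))
    return w


class TestLaplacian:
    def test_zero_matrix_gives_zero_laplacian(self):
        g = laplacian_from_weights(np.zeros((2, 2)))
        assert np.array_equal(g.laplacian, np.zeros((2, 2)))

    def test_single_edge(self):
        g = laplacian_from_weights([[0, 1], [1, 0]])
        assert np.allclose(g.laplacian, [[1, -1], [-1, 1]])

    def test_random_weights_row_sums_and_psd(self, random_symmetric_weights):
        g = laplacian_from_weights(random_symmetric_weights)
        assert np.abs(g.laplacian.sum(axis=1)).max() < 1e-10
        assert np.linalg.eigvalsh(g.laplacian).min() >= -1e-9

    def test_rejects_asymmetric(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(GraphValidationError, match=r"W\[0,1\]|W\[1,0\]"):
            laplacian_from_weights(w)

    def test_rejects_negative_and_nonsquare(self):
        with pytest.raises(GraphValidationError, match="negative"):
            laplacian_from_weights([[0, -1], [-1, 0]])
        with pytest.raises(GraphValidationError, match="square"):
            laplacian_from_weights(np.zeros((2, 3)))


class TestPenalty:
    def test_constant_vector_gives_zero(self):
        g = complete_graph(5)
        assert gsr_penalty(np.full(5, 3.7), g) == 0.0

    def test_single_edge_unit_difference(self):
        g = laplacian_from_weights([[0, 1], [1, 0]])
        assert gsr_penalty(np.array([1.0, 0.0]), g) == pytest.approx(1.0)

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(2, 21)
            a = rng.uniform(0, 1, size=(n, n))
            w = 0.5 * (a + a.T)
            np.fill_diagonal(w, 0)
            g = laplacian_from_weights(w)
            z = rng.normal(size=(rng.integers(1, 11), n))
            assert gsr_penalty(z, g) == pytest.approx(
                pairwise_penalty(z, w), abs=1e-8
            )

    def test_complete_graph_closed_form(self):
        # z = e_1 - e_2 on K_n: pairwise sum = 2n
        for n in (3, 5, 10):
            g = complete_graph(n)
            z = np.zeros(n)
            z[0], z[1] = 1.0, -1.0
            assert gsr_penalty(z, g) == pytest.approx(2 * n)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        z=hnp.arrays(float, (4, 6), elements=st.floats(-5, 5)),
        c=st.floats(-3, 3),
    )
    def test_quadratic_scaling(self, z, c):
        w = np.ones((6, 6)) - np.eye(6)
        g = laplacian_from_weights(w)
        p = gsr_penalty(z, g)
        assert gsr_penalty(c * z, g) == pytest.approx(c**2 * p, rel=1e-8, abs=1e-8)

    def test_shape_mismatch_raises(self):
        with pytest.raises(GraphValidationError, match="columns"):
            gsr_penalty(np.zeros((3, 4)), complete_graph(5))


class TestConstructors:
    def test_grid_trivial(self):
        g = grid_graph(1, 1)
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_grid_8x8(self):
        g = grid_graph(8, 8)
        assert g.n_nodes == 64
        assert g.n_edges == 112  # 8*7 + 8*7
        assert set(np.rint(g.degrees).astype(int)) == {2, 3, 4}

    def test_grid_2x3_degree_sequence(self):
        g = grid_graph(2, 3)
        assert sorted(np.rint(g.degrees).astype(int)) == [2, 2, 2, 2, 3, 3]

    def test_disjoint_pairs_basic(self):
        g = disjoint_pairs_graph(3)
        assert g.n_nodes == 6 and g.n_edges == 3
        assert connected_components(g, 0.0).n_components == 3

    def test_disjoint_single_pair_laplacian(self):
        g = disjoint_pairs_graph(1)
        assert np.allclose(g.laplacian, [[1, -1], [-1, 1]])

    def test_disjoint_pairs_block_diagonal(self):
        g = disjoint_pairs_graph(4)
        block = np.array([[1.0, -1.0], [-1.0, 1.0]])
        for p in range(4):
            sl = slice(2 * p, 2 * p + 2)
            assert np.allclose(g.laplacian[sl, sl], block)
        off = g.laplacian.copy()
        for p in range(4):
            off[2 * p : 2 * p + 2, 2 * p : 2 * p + 2] = 0
        assert np.all(off == 0)

    def test_complete_graph(self):
        g = complete_graph(10)
        assert np.allclose(g.degrees, 9)
        assert g.n_edges == 45
        assert np.allclose(g.laplacian, 10 * np.eye(10) - np.ones((10, 10)))

    @pytest.mark.parametrize("ctor,arg", [
        (grid_graph, (0, 3)), (disjoint_pairs_graph, (0,)), (complete_graph, (0,)),
    ])
    def test_constructors_reject_nonpositive(self, ctor, arg):
        with pytest.raises(GraphValidationError):
            ctor(*arg)

    def test_all_constructors_satisfy_laplacian_contract(self):
        for g in (grid_graph(3, 4), disjoint_pairs_graph(5), complete_graph(7)):
            assert np.abs(g.laplacian.sum(axis=1)).max() < 1e-10
            assert np.linalg.eigvalsh(g.laplacian).min() >= -1e-9


class TestAdaptiveKernel:
    def test_two_points_closed_form(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        g = adaptive_gaussian_kernel(x, KernelParams(k=1))
        assert g.weights[0, 1] == pytest.approx(np.exp(-0.5))

    def test_matches_scalar_oracle(self, rng):
        x = rng.normal(size=(5, 20))
        g = adaptive_gaussian_kernel(x, KernelParams(k=2))
        assert np.abs(g.weights - kernel_oracle(x, 2)).max() < 1e-12

    def test_symmetry_and_range(self, rng):
        for _ in range(10):
            x = rng.normal(size=(rng.integers(3, 12), 15))
            g = adaptive_gaussian_kernel(x, KernelParams(k=1))
            assert np.array_equal(g.weights, g.weights.T)
            assert g.weights.min() >= 0.0 and g.weights.max() <= 1.0
            assert np.abs(g.laplacian.sum(axis=1)).max() < 1e-10
            assert np.linalg.eigvalsh(g.laplacian).min() >= -1e-9

    def test_standardize_removes_gain_differences(self, rng):
        base = rng.normal(size=30)
        x = np.vstack([base, 5.0 * base + 2.0, rng.normal(size=30)])
        # affinely identical profiles hit the bandwidth floor (warned)
        with pytest.warns(RuntimeWarning, match="bandwidth"):
            g = adaptive_gaussian_kernel(x, KernelParams(k=1, standardize=True))
        # features 0 and 1 are affinely identical -> maximal affinity
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_duplicate_features_warn_and_use_floor(self):
        x = np.ones((3, 10))
        with pytest.warns(RuntimeWarning, match="bandwidth"):
            g = adaptive_gaussian_kernel(x, KernelParams(k=1))
        assert np.isfinite(g.weights).all()

    def test_too_few_features_raise(self):
        with pytest.raises(GraphValidationError, match="k=3"):
            adaptive_gaussian_kernel(np.eye(3), KernelParams(k=3))

    def test_nearest_neighbor_affinity_floor(self, rng):
        # every node's strongest edge is at least (1/2) exp(-1/2)
        x = rng.normal(size=(8, 25)) * rng.uniform(0.1, 10, size=(8, 1))
        g = adaptive_gaussian_kernel(x, KernelParams(k=1))
        assert g.weights.max(axis=1).min() >= 0.5 * np.exp(-0.5) - 1e-12


class TestComponents:
    def test_disjoint_pairs_threshold_zero(self):
        c = connected_components(disjoint_pairs_graph(3), 0.0)
        assert c.n_components == 3
        assert list(c.labels) == [0, 0, 1, 1, 2, 2]

    def test_complete_graph_threshold_semantics(self):
        g = complete_graph(5)
        assert connected_components(g, 0.0).n_components == 1
        # strict inequality removes unit-weight edges
        assert connected_components(g, 1.0).n_components == 5

    def test_matches_union_find_oracle(self, rng):
        def union_find(w, t):
            n = w.shape[0]
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if w[i, j] > t:
                        parent[find(i)] = find(j)
            return len({find(i) for i in range(n)})

        for _ in range(20):
            n = rng.integers(2, 12)
            a = rng.uniform(0, 1, size=(n, n)) * (rng.random((n, n)) < 0.4)
            w = 0.5 * (a + a.T)
            np.fill_diagonal(w, 0)
            g = laplacian_from_weights(w)
            t = rng.uniform(0, 0.8)
            assert connected_components(g, t).n_components == union_find(w, t)

    def test_labels_deterministic_lowest_first(self):
        w = np.zeros((4, 4))
        w[2, 3] = w[3, 2] = 1.0  # nodes 0,1 isolated
        c = connected_components(laplacian_from_weights(w), 0.0)
        assert list(c.labels) == [0, 1, 2, 2]

    def test_nn_union_keeps_strongest_edge_per_node(self, rng):
        x = rng.normal(size=(6, 30))
        g = adaptive_gaussian_kernel(x, KernelParams(k=1))
        sparse = nn_union_graph(g)
        for i in range(6):
            j = int(np.argmax(g.weights[i]))
            assert sparse.weights[i, j] == g.weights[i, j]
        assert np.count_nonzero(sparse.weights) <= np.count_nonzero(g.weights)


class TestGraphIO:
    def test_edgelist_roundtrip(self, random_symmetric_weights, tmp_path):
        g = laplacian_from_weights(random_symmetric_weights)
        path = tmp_path / "g.tsv"
        write_edgelist(g, path)
        g2 = read_edgelist(path, g.n_nodes)
        assert np.allclose(g.weights, g2.weights)
        first = path.read_text().splitlines()[0].split("\t")
        assert int(first[0]) < int(first[1])

    def test_graphml_roundtrip(self, tmp_path):
        g = grid_graph(3, 3)
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        g2 = read_graphml(path)
        assert np.allclose(g.weights, g2.weights)
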