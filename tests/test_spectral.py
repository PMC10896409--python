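import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sgft
from sgft.spectral import kneedle


def chord_knee(y, shape, direction):
    """Independent knee oracle: maximum distance from the chord.

    Normalises the curve to the unit square, maps it to canonical
    concave-increasing form, and returns the argmax of the vertical
    distance above the straight line joining the endpoints.
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    yn = (y - y.min()) / (y.max() - y.min())
    xn = np.arange(m) / (m - 1)
    flipped = False
    if shape == "convex" and direction == "decreasing":
        yn = 1 - yn
    elif shape == "convex" and direction == "increasing":
        yn, flipped = 1 - yn[::-1], True
    elif shape == "concave" and direction == "decreasing":
        yn, flipped = yn[::-1], True
    i = int(np.argmax(yn - xn))
    return m - 1 - i if flipped else i


class TestBuildKnnGraph:
    def test_collinear_points_nearest_neighbor_union(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = sgft.build_knn_graph(coords, ratio_neighbors=0.5)  # K = 1
        assert g.K == 1
        A = g.adjacency.toarray()
        # middle node's single NN is node 0 (tie broken by index), but the
        # union with node 2's relation gives edges (0,1) and (1,2)
        np.testing.assert_array_equal(A, [[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        np.testing.assert_array_equal(g.degrees, [1, 2, 1])

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sgft.build_knn_graph(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sgft.build_knn_graph(np.zeros((5, 2)) + np.arange(5)[:, None], 0.0)

    def test_grid_k_and_invariants(self, grid10):
        g, _ = grid10
        assert g.K == 10  # round(1.0 * sqrt(100))
        A = g.adjacency
        assert (abs(A - A.T)).nnz == 0
        assert A.diagonal().sum() == 0
        assert set(np.unique(A.toarray())) <= {0, 1}
        np.testing.assert_array_equal(
            g.degrees, np.asarray(A.sum(axis=1)).ravel()
        )


class TestLaplacian:
    def test_path_graph_matrix(self, path3):
        g, _ = path3
        np.testing.assert_array_equal(
            sgft.laplacian(g), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_row_sums_zero(self, grid10):
        g, _ = grid10
        np.testing.assert_allclose(sgft.laplacian(g).sum(axis=1), 0.0, atol=1e-12)


class TestEigendecompose:
    def test_path_graph_spectrum(self, path3):
        _, basis = path3
        np.testing.assert_allclose(basis.eigenvalues, [0.0, 1.0, 3.0], atol=1e-12)

    def test_constant_zero_mode(self, grid10):
        _, basis = grid10
        assert abs(basis.eigenvalues[0]) <= 1e-8
        np.testing.assert_allclose(basis.modes[:, 0], 1 / 10.0, atol=1e-10)

    def test_zero_multiplicity_counts_components(self):
        # two separated triangles: K=1 graph has two components
        coords = np.array(
            [[0, 0], [1, 0], [0.5, 0.8], [100, 0], [101, 0], [100.5, 0.8]],
            dtype=float,
        )
        g = sgft.build_knn_graph(coords, ratio_neighbors=0.5)
        basis = sgft.eigendecompose(sgft.laplacian(g))
        assert np.sum(np.abs(basis.eigenvalues) <= 1e-8) == 2
        assert basis.n_zero == 2

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sgft.eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_deterministic_sign_convention(self, grid10):
        g, basis = grid10
        again = sgft.eigendecompose(sgft.laplacian(g))
        np.testing.assert_array_equal(basis.modes, again.modes)
        np.testing.assert_array_equal(basis.eigenvalues, again.eigenvalues)
        # largest-magnitude entry of every mode is positive
        idx = np.argmax(np.abs(basis.modes), axis=0)
        assert np.all(basis.modes[idx, np.arange(basis.n)] > 0)


class TestKneedle:
    def test_cliff_curve_knee(self):
        y = np.array([100.0, 50, 25, 12, 11, 10.5, 10.2, 10])
        knee = kneedle(y, sensitivity=1, shape="convex", direction="decreasing")
        assert knee is not None
        assert abs(knee - 3) <= 1  # 1-based index 4 +- 1
        assert abs(knee - chord_knee(y, "convex", "decreasing")) <= 1

    def test_constant_curve_has_no_knee(self):
        assert kneedle(np.ones(10), 6, "convex", "decreasing") is None

    def test_mirrored_curve_same_knee(self):
        y = np.array([100.0, 50, 25, 12, 11, 10.5, 10.2, 10])
        k1 = kneedle(y, 1, "convex", "decreasing")
        k2 = kneedle(y[::-1], 1, "convex", "increasing")
        assert k1 is not None and k2 is not None
        assert k2 == len(y) - 1 - k1

    def test_flat_then_steep_breakpoint(self):
        y = np.concatenate([np.linspace(0, 1, 50), 1 + np.linspace(0.5, 60, 150)])
        knee = kneedle(y, 6, "convex", "increasing")
        oracle = chord_knee(y, "convex", "increasing")
        assert knee is not None
        assert abs(knee - oracle) <= 2
        assert abs(knee - 50) <= 2

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="length >= 4"):
            kneedle(np.array([1.0, 2.0, 3.0]), 6, "convex", "increasing")


class TestDetermineBands:
    def test_grid_bands_disjoint(self):
        coords = sgft.make_grid(20, 20)
        g = sgft.build_knn_graph(coords)
        w = np.linalg.eigvalsh(sgft.laplacian(g))
        n_low, n_high = sgft.determine_bands(w)
        assert n_low >= 1 and n_high >= 1
        assert n_low + n_high <= len(w) - 1

    def test_linear_curve_falls_back(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sgft"):
            n_low, n_high = sgft.determine_bands(np.arange(50, dtype=float))
        assert (n_low, n_high) == (5, 5)  # ceil(50/10)
        assert any("fallback" in r.message for r in caplog.records)


class TestTransforms:
    def test_constant_signal_energy_in_zero_mode(self, path3):
        _, basis = path3
        np.testing.assert_allclose(
            sgft.gft(basis, np.ones(3)), [np.sqrt(3), 0, 0], atol=1e-12
        )

    def test_igft_inverts_gft(self, path3):
        _, basis = path3
        np.testing.assert_allclose(
            sgft.igft(basis, np.array([np.sqrt(3), 0, 0])), 1.0, atol=1e-12
        )

    def test_length_mismatch_rejected(self, path3):
        _, basis = path3
        with pytest.raises(ValueError, match="does not match basis"):
            sgft.gft(basis, np.ones(4))
        with pytest.raises(ValueError, match="does not match basis"):
            sgft.igft(basis, np.ones(4))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_parseval_and_round_trip(self, grid10, seed):
        _, basis = grid10
        f = np.random.default_rng(seed).normal(size=basis.n)
        fh = sgft.gft(basis, f)
        assert abs(np.linalg.norm(fh) - np.linalg.norm(f)) <= 1e-8 * np.linalg.norm(f)
        np.testing.assert_allclose(sgft.igft(basis, fh), f, atol=1e-8)


class TestSmoothness:
    def test_eigenvector_smoothness_equals_eigenvalue(self, path3):
        g, basis = path3
        for k in range(3):
            assert abs(
                sgft.smoothness(g, basis.modes[:, k]) - basis.eigenvalues[k]
            ) <= 1e-10

    def test_constant_signal_has_zero_variation(self, grid10):
        g, _ = grid10
        assert sgft.smoothness(g, np.full(g.n_spots, 3.7)) == 0.0

    def test_quadratic_form_matches_pairwise_sum(self, grid10):
        g, _ = grid10
        rng = np.random.default_rng(1)
        A = g.adjacency.toarray()
        for _ in range(3):
            f = rng.normal(size=g.n_spots)
            pairwise = 0.5 * np.sum(A * (f[:, None] - f[None, :]) ** 2)
            assert abs(sgft.smoothness(g, f) - pairwise) <= 1e-10 * max(1, pairwise)
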