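import numpy as np
import pytest

import sgft


@pytest.fixture(scope="session")
def path3():
    """Path graph on 3 nodes with its exact spectrum (0, 1, 3)."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    g = sgft.build_knn_graph(coords, ratio_neighbors=0.5)  # K = 1
    basis = sgft.eigendecompose(sgft.laplacian(g))
    return g, basis


@pytest.fixture(scope="session")
def grid10():
    """10x10 lattice graph (K = 10) and its spectral basis."""
    coords = sgft.make_grid(10, 10)
    g = sgft.build_knn_graph(coords)
    basis = sgft.eigendecompose(sgft.laplacian(g))
    return g, basis


@pytest.fixture(scope="session")
def grid15():
    """15x15 lattice basis used for calibration checks."""
    coords = sgft.make_grid(15, 15)
    g = sgft.build_knn_graph(coords)
    basis = sgft.eigendecompose(sgft.laplacian(g))
    return g, basis


@pytest.fixture
def random_graph_factory():
    """Factory for irregular spot graphs of a given size."""

    def make(n, seed=0, ratio_neighbors=1.0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, size=(n, 2))
        g = sgft.build_knn_graph(coords, ratio_neighbors=ratio_neighbors)
        return g, sgft.eigendecompose(sgft.laplacian(g))

    return make


@pytest.fixture
def small_expression():
    """Tiny RawCounts fixture: 3 genes x 4 spots."""
    return sgft.RawCounts(
        values=np.array([[0, 2, 8, 0], [1, 1, 1, 1], [5, 0, 0, 3]]),
        gene_ids=["g1", "g2", "g3"],
        spot_ids=["s1", "s2", "s3", "s4"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )
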