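"""Spot-graph construction and the graph Fourier transform.

A tissue section profiled by a spot/cell/pixel technology is modelled as an
undirected graph: each spot is a node, and an edge joins two spots when
either is among the other's K nearest neighbours in physical (x, y) space.
The eigenvectors of the combinatorial Laplacian L = D - A are the Fourier
modes (FMs) of the tissue and the eigenvalues are their frequencies: a mode
with a small eigenvalue varies slowly over adjacent spots, a mode with a
large eigenvalue oscillates rapidly. Projecting a gene's expression vector
onto the modes (the graph Fourier transform, GFT) re-expresses the gene as
Fourier coefficients (FCs), the representation every downstream task in this
package operates on.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix, issparse
from scipy.spatial.distance import cdist

logger = logging.getLogger("sgft")

__all__ = [
    "SpotGraph",
    "SpectralBasis",
    "FCMatrix",
    "build_knn_graph",
    "laplacian",
    "eigendecompose",
    "determine_bands",
    "kneedle",
    "gft",
    "igft",
    "smoothness",
]

#: eigenvalues below this are treated as exactly zero (disconnected /
#: constant modes)
ZERO_EIGENVALUE_TOL = 1e-8


@dataclass
class SpotGraph:
    """Symmetric binary KNN graph over spot coordinates."""

    coords: np.ndarray
    K: int
    adjacency: csr_matrix
    degrees: np.ndarray

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


@dataclass
class SpectralBasis:
    """Laplacian eigendecomposition with the low/high frequency band split.

    ``eigenvalues`` are ascending (the first is 0 for any graph);
    ``modes`` has the corresponding orthonormal eigenvectors as columns.
    ``n_low`` / ``n_high`` delimit the frequency bands used by the spatial
    variability test: the low band is the first ``n_low`` nonzero-frequency
    modes, the high band the last ``n_high`` modes. ``basis_hash`` ties
    derived coefficient matrices back to the basis they were computed with.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    n_low: int
    n_high: int
    basis_hash: str = ""

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_zero(self) -> int:
        """Number of zero-frequency (per-component constant) modes."""
        return int(np.sum(self.eigenvalues <= ZERO_EIGENVALUE_TOL))

    def low_band(self) -> np.ndarray:
        """Indices of the low-frequency band (zero modes excluded)."""
        return np.arange(self.n_zero, self.n_zero + self.n_low)

    def high_band(self) -> np.ndarray:
        """Indices of the high-frequency band."""
        return np.arange(self.n - self.n_high, self.n)


@dataclass
class FCMatrix:
    """Gene x frequency Fourier-coefficient matrix tied to a basis."""

    values: np.ndarray
    gene_ids: list[str]
    basis_hash: str

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("FC row count does not match gene_ids")


def build_knn_graph(coords: np.ndarray, ratio_neighbors: float = 1.0) -> SpotGraph:
    """Build the symmetric binary KNN graph over spot coordinates.

    K = max(1, round(ratio_neighbors * sqrt(n))). An edge (i, j) exists when
    i is among the K nearest neighbours of j **or** vice versa (union
    symmetrisation), by Euclidean distance; distance ties are broken by spot
    index order. Self-loops are excluded.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    n = coords.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 spots to build a graph, got {n}")
    if ratio_neighbors <= 0:
        raise ValueError("ratio_neighbors must be positive")
    K = max(1, int(round(ratio_neighbors * math.sqrt(n))))
    K = min(K, n - 1)

    if n <= 4096:
        # exact, stable tie-break: argsort on full distance rows
        dist = cdist(coords, coords)
        np.fill_diagonal(dist, np.inf)
        nbrs = np.argsort(dist, axis=1, kind="stable")[:, :K]
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=K + 1).fit(coords)
        idx = nn.kneighbors(coords, return_distance=False)
        # drop self wherever it appears in the neighbour list
        nbrs = np.empty((n, K), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:K]
            nbrs[i] = row

    rows = np.repeat(np.arange(n), K)
    cols = nbrs.ravel()
    adj = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(np.int8)  # union symmetrisation
    adj.setdiag(0)
    adj.eliminate_zeros()
    degrees = np.asarray(adj.sum(axis=1)).ravel().astype(int)
    return SpotGraph(coords=coords, K=K, adjacency=adj.tocsr(), degrees=degrees)


def laplacian(g: SpotGraph) -> np.ndarray:
    """Combinatorial Laplacian L = D - A (dense, symmetric, zero row sums)."""
    A = g.adjacency.toarray().astype(float)
    return np.diag(g.degrees.astype(float)) - A


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| element positive.

    Ties resolve to the lowest row index (argmax returns the first maximum).
    """
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def eigendecompose(
    L: np.ndarray,
    sensitivity: float = 6.0,
    dense_limit: int = 5000,
    n_partial: int | None = None,
) -> SpectralBasis:
    """Eigendecompose a graph Laplacian into a :class:`SpectralBasis`.

    For n <= ``dense_limit`` a full dense symmetric decomposition is used
    (the regime of typical Visium sections). Above that, only the lowest and
    highest ``n_partial`` eigenpairs are computed with an iterative solver
    and the basis holds the two partial bands side by side; the band test
    then operates on those partial bands.

    Eigenvalues are ascending; eigenvector signs follow the
    largest-entry-positive convention so repeated runs are bit-identical.
    """
    if issparse(L):
        sym_err = abs(L - L.T).max()
    else:
        L = np.asarray(L, dtype=float)
        sym_err = float(np.max(np.abs(L - L.T))) if L.size else 0.0
    if sym_err > 1e-10:
        raise ValueError("Laplacian must be symmetric")
    n = L.shape[0]

    if n <= dense_limit:
        dense = L.toarray() if issparse(L) else L
        w, v = np.linalg.eigh(dense)
    else:
        from scipy.sparse.linalg import eigsh

        k = n_partial or max(64, int(4 * math.sqrt(n)))
        k = min(k, n // 2 - 1)
        Ls = L if issparse(L) else csr_matrix(L)
        w_lo, v_lo = eigsh(Ls.astype(float), k=k, sigma=0, which="LM")
        w_hi, v_hi = eigsh(Ls.astype(float), k=k, which="LA")
        order_lo, order_hi = np.argsort(w_lo), np.argsort(w_hi)
        w = np.concatenate([w_lo[order_lo], w_hi[order_hi]])
        v = np.concatenate([v_lo[:, order_lo], v_hi[:, order_hi]], axis=1)
        logger.info("eigendecompose: partial solver, 2x%d of %d eigenpairs", k, n)

    order = np.argsort(w, kind="stable")
    w = w[order]
    v = _fix_signs(v[:, order])
    w = np.where(np.abs(w) <= ZERO_EIGENVALUE_TOL, np.maximum(w, 0.0), w)

    if n >= 4:
        n_low, n_high = determine_bands(w, sensitivity=sensitivity)
    else:  # too few modes for knee detection; minimal bands (may overlap)
        n_low = n_high = 1
    return SpectralBasis(eigenvalues=w, modes=v, n_low=n_low, n_high=n_high)


# ---------------------------------------------------------------------------
# Kneedle knee/elbow detection
# ---------------------------------------------------------------------------

def kneedle(
    y: np.ndarray,
    sensitivity: float = 6.0,
    shape: str = "convex",
    direction: str = "increasing",
) -> int | None:
    """Kneedle knee/elbow detector; returns a 0-based index or ``None``.

    The curve (x = 0..m-1, y) is normalised to the unit square, mapped to
    canonical concave-increasing form according to ``shape``/``direction``,
    and the difference curve d = y_norm - x_norm is scanned: a local maximum
    of d is a knee if d drops below (local max - sensitivity * mean x-step)
    before the next local maximum (or the end of the curve).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("kneedle needs a 1-D vector of length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("kneedle input must be finite")
    if shape not in ("convex", "concave"):
        raise ValueError(f"unknown shape {shape!r}")
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")

    m = y.size
    span = y.max() - y.min()
    if span == 0:
        return None
    yn = (y - y.min()) / span
    xn = np.arange(m, dtype=float) / (m - 1)

    flipped_x = False
    # map to canonical concave increasing
    if shape == "convex" and direction == "decreasing":
        yn = 1.0 - yn
    elif shape == "convex" and direction == "increasing":
        yn = 1.0 - yn[::-1]
        flipped_x = True
    elif shape == "concave" and direction == "decreasing":
        yn = yn[::-1]
        flipped_x = True

    d = yn - xn
    step = 1.0 / (m - 1)
    threshold_drop = sensitivity * step

    # local maxima of the difference curve (plateaus take the first point)
    maxima = [
        i for i in range(1, m - 1)
        if d[i] >= d[i - 1] and d[i] > d[i + 1]
    ]
    knee = None
    for j, i in enumerate(maxima):
        thresh = d[i] - threshold_drop
        end = maxima[j + 1] if j + 1 < len(maxima) else m
        if np.any(d[i + 1 : end] < thresh):
            knee = i
            break
    if knee is None:
        return None
    if flipped_x:
        knee = m - 1 - knee
    return int(knee)


def determine_bands(
    eigenvalues: np.ndarray, sensitivity: float = 6.0
) -> tuple[int, int]:
    """Split the spectrum into low- and high-frequency bands via Kneedle.

    The ascending eigenvalue curve is scanned in the increasing direction
    to locate the low-frequency knee, and the reversed (decreasing) curve is
    scanned to locate the high-frequency knee; the number of modes up to
    each knee gives ``n_low`` / ``n_high``. The eigenvalue curve of a spot
    KNN graph is S-shaped — a steep shoulder of low frequencies, a plateau
    near the bulk, a convex rise into the extreme tail — so the low-band
    scan uses the concave shape (the early shoulder) and the high-band scan
    the convex shape on the reversed curve (the tail elbow). Falls back
    to ceil(n/10) for a band whose knee is not found, with a warning. The
    bands are clipped to stay disjoint (zero modes excluded from the low
    band by callers via :meth:`SpectralBasis.low_band`).
    """
    w = np.asarray(eigenvalues, dtype=float)
    n = w.size
    if n < 4:
        raise ValueError("need at least 4 eigenvalues")
    fallback = max(1, math.ceil(n / 10))

    k_low = kneedle(w, sensitivity=sensitivity, shape="concave", direction="increasing")
    if k_low is None or k_low < 1:
        logger.warning("determine_bands: no low-frequency knee; fallback n_low=%d", fallback)
        n_low = fallback
    else:
        n_low = k_low

    k_high = kneedle(w[::-1], sensitivity=sensitivity, shape="convex", direction="decreasing")
    if k_high is None or k_high < 1:
        logger.warning("determine_bands: no high-frequency knee; fallback n_high=%d", fallback)
        n_high = fallback
    else:
        n_high = k_high

    n_zero = int(np.sum(w <= ZERO_EIGENVALUE_TOL))
    max_total = n - n_zero
    if n_low + n_high > max_total:  # keep bands disjoint
        scale = max_total / (n_low + n_high)
        n_low = max(1, int(n_low * scale))
        n_high = max(1, min(max_total - n_low, int(n_high * scale)))
    return int(n_low), int(n_high)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def gft(basis: SpectralBasis, signal: np.ndarray) -> np.ndarray:
    """Graph Fourier transform: project signal(s) onto the Fourier modes.

    ``signal`` may be a length-n vector or an (n, m) matrix of m signals in
    columns; returns U^T signal with the same shape.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != basis.n:
        raise ValueError(
            f"signal length {signal.shape[0]} does not match basis size {basis.n}"
        )
    return basis.modes.T @ signal


def igft(basis: SpectralBasis, fcs: np.ndarray) -> np.ndarray:
    """Inverse graph Fourier transform: U fcs."""
    fcs = np.asarray(fcs, dtype=float)
    if fcs.shape[0] != basis.n:
        raise ValueError(
            f"coefficient length {fcs.shape[0]} does not match basis size {basis.n}"
        )
    return basis.modes @ fcs


def smoothness(g: SpotGraph, signal: np.ndarray) -> float:
    """Total variation f^T L f = 1/2 sum_ij a_ij (f_i - f_j)^2 (>= 0)."""
    f = np.asarray(signal, dtype=float)
    if f.shape[0] != g.n_spots:
        raise ValueError("signal length does not match graph size")
    quad = float(f @ (g.degrees * f) - f @ (g.adjacency @ f))
    return max(quad, 0.0)


def basis_hash(coords: np.ndarray, K: int, solver: str = "dense") -> str:
    """Short identifier binding FC matrices to the graph/solver they used."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(coords, dtype=float).tobytes())
    h.update(f"|K={K}|{solver}".encode())
    return h.hexdigest()[:12]
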