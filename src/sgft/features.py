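"""Frequency-domain terms for plugging into external ML methods.

These are stand-alone building blocks that inject spatial-frequency
information into third-party frameworks; the host frameworks' training
loops are deliberately out of scope:

* :func:`spot_fc_features` — spot-similarity Fourier features to concatenate
  onto an expression matrix before graph-convolutional domain clustering.
* :func:`fc_cost_matrix` / :func:`fuse_costs` — a cosine-distance cost
  between annotation and spot FC profiles, blended with a base optimal
  transport cost as beta*C + (1-beta)*C_update (default beta 0.8).
* :func:`frequency_similarity_terms` — gene- and spot-level cosine
  similarity sums in the frequency domain, for augmenting an alignment
  objective (callers apply their own weights).
* :func:`spreading_entropy` — Shannon entropy of squared-normalised FCs,
  a regulariser that is 0 for a single-mode signal and log(n_fc) for a
  uniformly spread one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .spectral import SpectralBasis

__all__ = [
    "FrequencyFeatureSet",
    "CostMatrices",
    "spot_fc_features",
    "augment_features",
    "fc_cost_matrix",
    "fuse_costs",
    "frequency_similarity_terms",
    "spreading_entropy",
]

#: default number of Fourier coefficients for feature augmentation
DEFAULT_N_FC = 1000


@dataclass
class FrequencyFeatureSet:
    """Spot-major Fourier features of the spot-similarity matrix."""

    spot_fcs: np.ndarray  # spot x n_fc
    n_fc: int
    basis_hash: str = ""


@dataclass
class CostMatrices:
    """Base and frequency-updated transport costs with a blending weight."""

    base_cost: np.ndarray
    update_cost: np.ndarray
    beta: float = 0.8

    def __post_init__(self) -> None:
        self.base_cost = np.asarray(self.base_cost, dtype=float)
        self.update_cost = np.asarray(self.update_cost, dtype=float)
        if self.base_cost.shape != self.update_cost.shape:
            raise ValueError("cost matrices must share a shape")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


def spot_fc_features(
    expr_spot_major: np.ndarray,
    basis: SpectralBasis,
    n_fc: int = DEFAULT_N_FC,
) -> FrequencyFeatureSet:
    """Fourier features of the spot cosine-similarity matrix.

    X_s = X X^T is the spot similarity matrix of the spot x gene input;
    its GFT U^T X_s is truncated to the first ``n_fc`` frequency rows
    (capped at n) and returned spot-major, ready to concatenate onto the
    expression matrix via :func:`augment_features`.
    """
    X = np.asarray(expr_spot_major, dtype=float)
    if X.shape[0] != basis.n:
        raise ValueError("spot count does not match basis")
    if n_fc > basis.n:
        raise ValueError(f"n_fc={n_fc} exceeds basis size {basis.n}")
    Xs = X @ X.T
    hat = basis.modes.T @ Xs  # frequency x spot
    return FrequencyFeatureSet(
        spot_fcs=hat[:n_fc].T, n_fc=n_fc, basis_hash=basis.basis_hash
    )


def augment_features(
    expr_spot_major: np.ndarray, feats: FrequencyFeatureSet
) -> np.ndarray:
    """Concatenate Fourier features onto a spot x gene matrix column-wise."""
    X = np.asarray(expr_spot_major, dtype=float)
    if X.shape[0] != feats.spot_fcs.shape[0]:
        raise ValueError("spot counts differ")
    return np.concatenate([X, feats.spot_fcs], axis=1)


def fc_cost_matrix(
    annotation_fcs: np.ndarray, spot_fcs: np.ndarray
) -> np.ndarray:
    """Cosine-distance cost between annotation and spot FC profiles.

    Entry (t, b) = 1 - cosine(annotation_t, spot_b), in [0, 2].
    """
    A = np.asarray(annotation_fcs, dtype=float)
    B = np.asarray(spot_fcs, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("FC dimensions differ")
    if np.any(np.linalg.norm(A, axis=1) == 0) or np.any(np.linalg.norm(B, axis=1) == 0):
        raise ValueError("zero rows have undefined cosine distance")
    return 1.0 - cosine_similarity(A, B)


def fuse_costs(cm: CostMatrices) -> np.ndarray:
    """Blend the costs: beta * C + (1 - beta) * C_update."""
    return cm.beta * cm.base_cost + (1.0 - cm.beta) * cm.update_cost


def _colwise_cosine_sum(A: np.ndarray, B: np.ndarray) -> float:
    """Sum of column-wise cosines; zero-norm columns contribute 0."""
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    dots = np.sum(A * B, axis=0)
    denom = na * nb
    ok = denom > 0
    return float(np.sum(dots[ok] / denom[ok]))


def frequency_similarity_terms(
    x_recon: np.ndarray,
    x_ref: np.ndarray,
    basis: SpectralBasis,
    n_fc: int | None = None,
) -> tuple[float, float]:
    """Gene- and spot-level frequency-domain cosine similarity sums.

    For spot x gene matrices: the gene term sums cosine(U^T x_recon[:, k],
    U^T x_ref[:, k]) over genes; the spot term does the same over the
    columns of the transformed spot-similarity matrices U^T (X X^T).
    ``n_fc`` truncates the basis (default: all modes — with the full basis
    the gene term equals the vertex-domain cosine sum, since an orthonormal
    transform preserves inner products). Both terms are returned unweighted.
    """
    Xr = np.asarray(x_recon, dtype=float)
    Xf = np.asarray(x_ref, dtype=float)
    if Xr.shape != Xf.shape:
        raise ValueError("matrices must share a shape")
    if Xr.shape[0] != basis.n:
        raise ValueError("spot count does not match basis")
    U = basis.modes if n_fc is None else basis.modes[:, :n_fc]
    gene_term = _colwise_cosine_sum(U.T @ Xr, U.T @ Xf)
    spot_term = _colwise_cosine_sum(U.T @ (Xr @ Xr.T), U.T @ (Xf @ Xf.T))
    return gene_term, spot_term


def spreading_entropy(fcs: np.ndarray) -> float:
    """Shannon entropy of squared-normalised FCs, summed over channels.

    For each channel column f, p_k = f_k^2 / ||f||_2^2 and the entropy is
    -sum p_k log p_k (natural log, 0*log 0 = 0). A one-hot spectrum gives
    0; a uniform spread over n_fc modes gives log(n_fc). Invariant to sign
    flips and positive rescaling.
    """
    F = np.asarray(fcs, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    sq = F**2
    totals = sq.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("all-zero channel has undefined entropy")
    p = sq / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum())
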