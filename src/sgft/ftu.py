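"""Functional tissue unit (FTU) identification from SVG clusters.

SVGs that share a spatial pattern load on similar low-frequency Fourier
modes, so clustering genes in low-frequency FC space groups them into
pattern families. Each family is mapped back to tissue space through its
pseudo-expression (the per-spot sum of log1p expression over the family's
genes) and a deterministic 1-D 2-means split: the high-mean cluster of
spots is the family's FTU. FTUs are allowed to overlap (polyfunctional
regions), but the clustering resolution is chosen to minimise the mean
pairwise overlap

    2 * sum_{k<l} |S_k ∩ S_l| / (n_res * (n_res - 1)),

scanned over a resolution grid for the Louvain algorithm.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph
import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .io import ExpressionMatrix

logger = logging.getLogger("sgft")

__all__ = [
    "FTUResult",
    "cluster_svgs",
    "pseudo_expression",
    "assign_spots",
    "overlap_objective",
    "optimize_resolution",
    "DEFAULT_RES_GRID",
]

DEFAULT_RES_GRID = tuple(np.round(np.arange(0.2, 3.01, 0.2), 2))


@dataclass
class FTUResult:
    """Outcome of FTU identification at the selected resolution."""

    resolution: float
    gene_clusters: dict[str, int]
    spot_sets: list[set[str]]
    overlap: float
    pseudo: np.ndarray  # cluster x spot


def cluster_svgs(
    fc_low: np.ndarray,
    resolution: float,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Louvain clustering of SVGs on their low-frequency FC vectors.

    A gene KNN graph (cosine similarity, k = min(n_neighbors, n_svg - 1),
    union-symmetrised, edges weighted by similarity clipped at 0) is
    partitioned by the Louvain algorithm at the given resolution with a
    fixed RNG seed. Labels are contiguous from 1.
    """
    fc_low = np.asarray(fc_low, dtype=float)
    m = fc_low.shape[0]
    if m < 2:
        raise ValueError("need at least 2 SVGs to cluster")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    k = min(n_neighbors, m - 1)

    sim = cosine_similarity(fc_low)
    np.fill_diagonal(sim, -np.inf)
    nbrs = np.argsort(-sim, axis=1, kind="stable")[:, :k]

    edges: set[tuple[int, int]] = set()
    for i in range(m):
        for j in nbrs[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    edge_list = sorted(edges)
    weights = [max(sim[i, j], 0.0) for i, j in edge_list]

    g = igraph.Graph(n=m, edges=edge_list)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=weights, resolution=resolution)
    labels = np.asarray(part.membership, dtype=int) + 1
    return labels


def pseudo_expression(expr: ExpressionMatrix, gene_set: set[str]) -> np.ndarray:
    """Per-spot pseudo-expression of a gene set: sum of log1p values.

    log1p keeps the sum defined at zero expression while preserving the
    ordering and additivity of a plain log sum.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"gene(s) not in expression matrix: {sorted(missing)[:5]}")
    rows = [index[g] for g in sorted(gene_set)]
    return np.log1p(expr.values[rows]).sum(axis=0)


def assign_spots(pseudo: np.ndarray, seed: int = 0) -> np.ndarray:
    """1-D 2-means split of pseudo-expression; returns high-cluster indices.

    Centers are initialised deterministically at the min and max values
    (``seed`` is accepted for interface uniformity; the algorithm is
    deterministic). Returns the indices of spots in the cluster with the
    larger mean. The split is invariant to increasing affine transforms.
    """
    v = np.asarray(pseudo, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need at least 2 spots with non-identical values")
    lo, hi = float(v.min()), float(v.max())
    for _ in range(100):
        assign_hi = np.abs(v - hi) < np.abs(v - lo)
        new_lo = v[~assign_hi].mean() if (~assign_hi).any() else lo
        new_hi = v[assign_hi].mean() if assign_hi.any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return np.flatnonzero(np.abs(v - hi) < np.abs(v - lo))


def overlap_objective(spot_sets: list[set]) -> float:
    """Mean pairwise intersection size: 2 sum_{k<l} |S_k ∩ S_l| / (m(m-1)).

    Zero exactly when the sets are pairwise disjoint; symmetric in order.
    """
    m = len(spot_sets)
    if m < 2:
        raise ValueError("need at least 2 spot sets")
    total = sum(
        len(spot_sets[k] & spot_sets[l]) for k in range(m) for l in range(k + 1, m)
    )
    return 2.0 * total / (m * (m - 1))


def optimize_resolution(
    fc_low: np.ndarray,
    expr: ExpressionMatrix,
    res_grid: tuple[float, ...] | list[float] = DEFAULT_RES_GRID,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    n_neighbors: int = 15,
) -> FTUResult:
    """Scan Louvain resolutions and keep the FTU set with minimal overlap.

    ``fc_low`` rows must align with ``gene_ids`` (default: ``expr.gene_ids``,
    i.e. the expression matrix is already restricted to SVGs). Resolutions
    yielding fewer than 2 gene clusters are skipped; ties in the overlap
    objective resolve to the smallest resolution.
    """
    if len(res_grid) == 0:
        raise ValueError("res_grid must be non-empty")
    gene_ids = list(gene_ids) if gene_ids is not None else list(expr.gene_ids)
    if len(gene_ids) != fc_low.shape[0]:
        raise ValueError("gene_ids length does not match fc_low rows")

    best: FTUResult | None = None
    for res in sorted(set(float(r) for r in res_grid)):
        labels = cluster_svgs(fc_low, res, n_neighbors=n_neighbors, seed=seed)
        n_clusters = labels.max()
        if n_clusters < 2:
            logger.info("optimize_resolution: res=%.2g gives %d cluster(s); skipped",
                        res, n_clusters)
            continue
        spot_sets: list[set[str]] = []
        pseudo_rows = []
        for c in range(1, n_clusters + 1):
            genes = {g for g, lab in zip(gene_ids, labels) if lab == c}
            pseudo = pseudo_expression(expr, genes)
            pseudo_rows.append(pseudo)
            idx = assign_spots(pseudo, seed=seed)
            spot_sets.append({expr.spot_ids[i] for i in idx})
        overlap = overlap_objective(spot_sets)
        if best is None or overlap < best.overlap:
            best = FTUResult(
                resolution=res,
                gene_clusters=dict(zip(gene_ids, (int(l) for l in labels))),
                spot_sets=spot_sets,
                overlap=overlap,
                pseudo=np.vstack(pseudo_rows),
            )
    if best is None:
        raise ValueError(
            "every resolution produced fewer than 2 SVG clusters; widen res_grid"
        )
    logger.info("optimize_resolution: chose res=%.2g (overlap=%.3g, %d FTUs)",
                best.resolution, best.overlap, len(best.spot_sets))
    return best
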