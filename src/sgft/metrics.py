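"""Benchmarking metrics: set overlap, partition agreement, image similarity.

:func:`set_metrics` scores a predicted gene set against a reference set
(Jaccard, precision, recall, F1, Tversky). :func:`ari` is the adjusted Rand
index between two spot partitions. :func:`ssim` is the windowed structural
similarity index between two pattern images — the mean over dense 8x8
sliding windows of the luminance/contrast/structure product

    l^alpha * c^beta * s^gamma,
    l = (2 mx my + C1) / (mx^2 + my^2 + C1),
    c = (2 sx sy + C2) / (sx^2 + sy^2 + C2),
    s = (sxy + C3) / (sx sy + C3),

with the standard stabilizers C1 = (0.01 R)^2, C2 = (0.03 R)^2, C3 = C2/2
for R = 1 after global min-max rescaling of each image to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger("sgft")

__all__ = ["MetricReport", "set_metrics", "ari", "ssim"]


@dataclass
class MetricReport:
    """Set-overlap scores for a predicted vs reference gene set."""

    jaccard: float
    precision: float
    recall: float
    f1: float
    tversky: float
    tp: int
    fp: int
    fn: int


def set_metrics(
    predicted: set,
    truth: set,
    tversky_alpha: float = 0.5,
    tversky_beta: float = 0.5,
) -> MetricReport:
    """Score a predicted set against a non-empty reference set.

    Tversky = TP / (TP + alpha*FP + beta*FN); with alpha = beta = 1 it
    collapses to the Jaccard index. An empty prediction yields precision 0
    with a warning.
    """
    predicted, truth = set(predicted), set(truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    if not predicted:
        logger.warning("set_metrics: empty prediction; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    jaccard = tp / (tp + fp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    tversky = tp / (tp + tversky_alpha * fp + tversky_beta * fn) if tp + fp + fn else 1.0
    return MetricReport(
        jaccard=jaccard, precision=precision, recall=recall,
        f1=f1, tversky=tversky, tp=tp, fp=fp, fn=fn,
    )


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (1 iff identical up to
    relabeling, expectation 0 under independent random partitions)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 labels")
    return float(adjusted_rand_score(a, b))


def _rescale01(img: np.ndarray) -> np.ndarray:
    span = img.max() - img.min()
    return np.zeros_like(img) if span == 0 else (img - img.min()) / span


def ssim(
    img_a: np.ndarray,
    img_b: np.ndarray,
    window: int = 8,
    exponents: tuple[float, float, float] = (1.0, 1.0, 1.0),
    constants: tuple[float, float, float] | None = None,
) -> float:
    """Structural similarity of two images over dense sliding windows.

    Images are globally min-max rescaled to [0, 1] before comparison;
    window statistics use sample (ddof=1) variance and covariance. Stride
    is 1. Returns the mean windowed l*c*s product; 1.0 exactly for
    identical images.
    """
    A = _rescale01(np.asarray(img_a, dtype=float))
    B = _rescale01(np.asarray(img_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("images must share a shape")
    if A.ndim != 2 or min(A.shape) < window:
        raise ValueError(f"images must be 2-D with both dimensions >= window={window}")
    if constants is None:
        C1, C2 = 0.01**2, 0.03**2  # (0.01 R)^2, (0.03 R)^2 with R = 1
        C3 = C2 / 2.0
    else:
        C1, C2, C3 = constants
    al, be, ga = exponents

    wa = sliding_window_view(A, (window, window)).reshape(-1, window * window)
    wb = sliding_window_view(B, (window, window)).reshape(-1, window * window)
    npix = window * window
    mx = wa.mean(axis=1)
    my = wb.mean(axis=1)
    da = wa - mx[:, None]
    db = wb - my[:, None]
    # identical code path for var and cov => bit-identical when A is B
    vx = np.sum(da * da, axis=1) / (npix - 1)
    vy = np.sum(db * db, axis=1) / (npix - 1)
    cxy = np.sum(da * db, axis=1) / (npix - 1)
    sx = np.sqrt(vx)
    sy = np.sqrt(vy)

    l = (2 * mx * my + C1) / (mx**2 + my**2 + C1)
    c = (2 * sx * sy + C2) / (vx + vy + C2)
    s = (cxy + C3) / (sx * sy + C3)
    vals = np.sign(l) * np.abs(l) ** al * np.sign(c) * np.abs(c) ** be
    vals = vals * np.sign(s) * np.abs(s) ** ga
    return float(vals.mean())
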