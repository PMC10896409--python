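"""Low-pass enhancement of noisy spatial signals.

Measured expression f is modelled as a smooth tissue signal plus noise.
The denoised signal is the minimiser of

    ||f* - f||^2 + c * f*^T L f*,

which balances fidelity to the measurement against total variation on the
spot graph. The closed-form solution is f* = U (I + c Lambda)^-1 U^T f:
transform to the frequency domain, shrink each coefficient by the low-pass
weight 1 / (1 + c * lambda_k), and transform back (iGFT). In practice the
spectrum is additionally truncated to the first k_low = round(ratio_fms *
sqrt(n)) low-frequency coefficients, which removes high-frequency content
entirely; ``keep_all`` disables truncation and gives the exact minimiser.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .io import ExpressionMatrix
from .spectral import SpectralBasis, gft, igft

logger = logging.getLogger("sgft")

__all__ = ["FilterConfig", "low_pass_weights", "enhance_signal", "enhance_matrix"]


@dataclass
class FilterConfig:
    """Low-pass filter settings.

    ``c`` weights the smoothness penalty (Visium default 0.005);
    ``ratio_fms`` sets the truncation k_low = round(ratio_fms * sqrt(n))
    (default 15); ``keep_all`` disables truncation (exact closed form);
    ``clip_negative`` zeroes small negative outputs of the linear filter
    on request (never silently).
    """

    c: float = 0.005
    ratio_fms: float = 15.0
    keep_all: bool = False
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.ratio_fms <= 0:
            raise ValueError("ratio_fms must be positive")

    def k_low(self, n: int) -> int:
        k = int(round(self.ratio_fms * math.sqrt(n)))
        if k < 1:
            raise ValueError("ratio_fms too small: no coefficients kept")
        if k > n:
            raise ValueError(f"k_low={k} exceeds basis size {n}")
        return k


def low_pass_weights(eigenvalues: np.ndarray, c: float) -> np.ndarray:
    """Filter gains 1 / (1 + c * lambda_k): in (0, 1], non-increasing."""
    if c <= 0:
        raise ValueError("c must be positive")
    w = np.asarray(eigenvalues, dtype=float)
    return 1.0 / (1.0 + c * w)


def enhance_signal(
    basis: SpectralBasis, signal: np.ndarray, cfg: FilterConfig
) -> np.ndarray:
    """Low-pass filter one signal (or a column-stacked matrix of signals).

    GFT -> multiply the retained coefficients by the low-pass gains, zero
    the rest (all coefficients retained under ``keep_all``) -> iGFT. With
    ``keep_all`` the output is the unique minimiser of
    ||f - f_g||^2 + c f^T L f.
    """
    fcs = gft(basis, signal)
    gains = low_pass_weights(basis.eigenvalues, cfg.c)
    if not cfg.keep_all:
        k = cfg.k_low(basis.n)
        mask = np.zeros(basis.n)
        mask[:k] = 1.0
        gains = gains * mask
    out = igft(basis, (fcs.T * gains).T if fcs.ndim > 1 else fcs * gains)
    if cfg.clip_negative:
        out = np.clip(out, 0.0, None)
    return out


def enhance_matrix(
    expr: ExpressionMatrix,
    basis: SpectralBasis,
    cfg: FilterConfig,
    genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Apply :func:`enhance_signal` to each selected gene row.

    Unselected genes pass through unchanged. The returned matrix records
    the filter configuration in its ``meta``.
    """
    if expr.n_spots != basis.n:
        raise ValueError("expression spot count does not match basis")
    if genes is None:
        sel = np.ones(expr.n_genes, dtype=bool)
    else:
        index = {g: i for i, g in enumerate(expr.gene_ids)}
        unknown = [g for g in genes if g not in index]
        if unknown:
            raise ValueError(f"unknown gene(s) in subset: {unknown[:5]}")
        sel = np.zeros(expr.n_genes, dtype=bool)
        sel[[index[g] for g in genes]] = True

    values = expr.values.copy()
    values[sel] = enhance_signal(basis, expr.values[sel].T, cfg).T
    meta = dict(expr.meta)
    meta["enhancement"] = {
        "c": cfg.c,
        "ratio_fms": cfg.ratio_fms,
        "keep_all": cfg.keep_all,
        "clip_negative": cfg.clip_negative,
        "n_genes_enhanced": int(sel.sum()),
    }
    return replace(expr, values=values, normalized=False, meta=meta)
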