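"""Reading, filtering and normalising spot-level expression matrices.

The canonical in-memory orientation throughout the package is gene-major:
a ``values`` array of shape ``(n_genes, n_spots)`` together with parallel
``gene_ids`` / ``spot_ids`` lists and a ``(n_spots, 2)`` coordinate array.
Two on-disk layouts are supported: Matrix Market coordinate triplets with
``features.tsv`` / ``barcodes.tsv`` sidecars (10x style) and plain delimited
tables (first column = gene IDs, header row = spot IDs). Coordinates are a
delimited table with columns ``spot_id, x, y``; the spot order of that table
defines the spot order of the loaded matrix.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("sgft")

__all__ = [
    "RawCounts",
    "ExpressionMatrix",
    "load_expression",
    "load_coordinates",
    "filter_genes",
    "normalize",
    "read_delimited",
    "write_delimited",
    "write_table",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} ID {dup!r}")


@dataclass
class RawCounts:
    """Gene x spot count matrix with spot coordinates.

    Invariants (checked on construction): non-negative values, unique IDs,
    and consistent shapes between values, IDs and coordinates.
    """

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.spot_ids = list(self.spot_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x spot matrix")
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be spot x 2")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.spot_ids, "spot")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class ExpressionMatrix:
    """Gene x spot expression values, optionally normalised.

    ``normalized`` records whether :func:`normalize` has been applied;
    ``meta`` carries free-form provenance (filter settings, enhancement
    configuration, ...).
    """

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.spot_ids = list(self.spot_ids)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError("values shape does not match gene/spot IDs")
        if self.normalized and not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


def load_coordinates(coords_path: str | os.PathLike) -> pd.DataFrame:
    """Read a spot coordinate table (columns ``spot_id, x, y``).

    Delimiter is sniffed (tab or comma). A header row is expected; if the
    expected column names are absent the first three columns are used
    positionally.
    """
    df = pd.read_csv(coords_path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if {"spot_id", "x", "y"}.issubset(cols):
        df.columns = cols
        df = df[["spot_id", "x", "y"]]
    else:
        if df.shape[1] < 3:
            raise ValueError(
                f"coordinate table {coords_path} needs at least 3 columns (spot_id, x, y)"
            )
        df = df.iloc[:, :3]
        df.columns = ["spot_id", "x", "y"]
    df["spot_id"] = df["spot_id"].astype(str)
    _check_unique(list(df["spot_id"]), "spot")
    return df


def read_delimited(path: str | os.PathLike, transpose: bool = False) -> pd.DataFrame:
    """Read a delimited matrix (rows = genes unless ``transpose``)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, comment="#")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_sidecar(path: str) -> list[str]:
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def load_expression(
    path: str | os.PathLike,
    fmt: str,
    coords_path: str | os.PathLike,
    transpose: bool = False,
) -> RawCounts:
    """Load an expression matrix plus coordinates into :class:`RawCounts`.

    Parameters
    ----------
    path
        Matrix file: an ``.mtx`` triplet (``fmt="mtx"``, with
        ``features.tsv``/``genes.tsv`` and ``barcodes.tsv`` sidecars in the
        same directory) or a delimited table (``fmt="delimited"``).
    fmt
        ``"mtx"`` or ``"delimited"``.
    coords_path
        Coordinate table; its row order defines the spot order. Spots in the
        matrix without coordinates are dropped with a warning.
    transpose
        For delimited input whose rows are spots rather than genes.
    """
    if fmt == "mtx":
        try:
            mat = mmread(os.fspath(path))
        except ValueError as exc:
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        d = os.path.dirname(os.fspath(path))
        feat = next(
            (os.path.join(d, f) for f in ("features.tsv", "genes.tsv") if os.path.exists(os.path.join(d, f))),
            None,
        )
        barc = os.path.join(d, "barcodes.tsv")
        if feat is None or not os.path.exists(barc):
            raise FileNotFoundError(
                f"mtx input requires features.tsv/genes.tsv and barcodes.tsv next to {path}"
            )
        gene_ids = _read_sidecar(feat)
        spot_ids = _read_sidecar(barc)
        if transpose:
            dense = dense.T
        if dense.shape != (len(gene_ids), len(spot_ids)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(gene_ids)} features, {len(spot_ids)} barcodes)"
            )
        df = pd.DataFrame(dense, index=gene_ids, columns=spot_ids)
    elif fmt == "delimited":
        df = read_delimited(path, transpose=transpose)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'mtx' or 'delimited')")

    _check_unique(list(df.index), "gene")
    _check_unique(list(df.columns), "spot")

    coords = load_coordinates(coords_path)
    keep = [s for s in coords["spot_id"] if s in set(df.columns)]
    missing = set(df.columns) - set(coords["spot_id"])
    if missing:
        logger.warning(
            "dropping %d spot(s) without coordinates (e.g. %s)",
            len(missing), sorted(missing)[0],
        )
    if not keep:
        raise ValueError("no spots shared between expression matrix and coordinate table")
    coords = coords.set_index("spot_id").loc[keep]
    return RawCounts(
        values=df[keep].to_numpy(),
        gene_ids=list(df.index),
        spot_ids=keep,
        coords=coords[["x", "y"]].to_numpy(dtype=float),
    )


def filter_genes(rc: RawCounts, min_spots: int = 10) -> RawCounts:
    """Drop genes expressed (nonzero) in fewer than ``min_spots`` spots.

    Gene order is preserved. The operation is idempotent.
    """
    if min_spots < 0:
        raise ValueError("min_spots must be >= 0")
    keep = np.count_nonzero(rc.values, axis=1) >= min_spots
    if not keep.any():
        raise ValueError(f"all genes removed by min_spots={min_spots} filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_genes: removed %d/%d genes (min_spots=%d)",
                    n_dropped, rc.n_genes, min_spots)
    return RawCounts(
        values=rc.values[keep],
        gene_ids=[g for g, k in zip(rc.gene_ids, keep) if k],
        spot_ids=rc.spot_ids,
        coords=rc.coords,
    )


def normalize(
    rc: RawCounts, scale: float = 1e6, log_transform: bool = True
) -> ExpressionMatrix:
    """Depth-normalise counts (counts per ``scale`` reads) and log-transform.

    Each spot's counts are divided by the spot total and multiplied by
    ``scale`` (CPM for the default 1e6), then ``log(1 + x)`` is applied when
    ``log_transform``. Spots with zero total count are dropped with a warning.
    """
    totals = rc.values.sum(axis=0)
    nonzero = totals > 0
    values, spot_ids, coords = rc.values, rc.spot_ids, rc.coords
    if not np.all(nonzero):
        logger.warning("normalize: dropping %d spot(s) with zero total count",
                       int((~nonzero).sum()))
        values = values[:, nonzero]
        spot_ids = [s for s, k in zip(spot_ids, nonzero) if k]
        coords = coords[nonzero]
        totals = totals[nonzero]
    out = values / totals * scale
    if log_transform:
        out = np.log1p(out)
    return ExpressionMatrix(
        values=out,
        gene_ids=list(rc.gene_ids),
        spot_ids=spot_ids,
        coords=coords,
        normalized=True,
        meta={"scale": scale, "log_transform": log_transform},
    )


def write_delimited(expr: ExpressionMatrix | RawCounts, path: str | os.PathLike) -> None:
    """Write a gene x spot matrix as TSV (genes as rows)."""
    pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.spot_ids).to_csv(
        path, sep="\t", index_label="gene"
    )


def write_table(df: pd.DataFrame, path: str | os.PathLike, metadata: dict | None = None) -> None:
    """Write a result table as TSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
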