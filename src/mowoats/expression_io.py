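"""Reading/writing gene-expression matrices and cluster-ordered (Eisen-style) exports.

The on-disk format is delimited text with a header row: one identifier
column (first by default) followed by numeric feature columns, one row per
gene.  Matrices are assumed complete and pre-normalized (e.g. log2 ratios);
missing or non-numeric cells are rejected rather than imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, ShapeError, UniquenessError

__all__ = [
    "ExpressionMatrix",
    "load_expression_matrix",
    "save_expression_matrix",
    "export_cluster_heatmap",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An n-gene x f-feature expression matrix with row/column labels.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique identifiers, one per row.
    feature_labels : sequence of str
        Column labels (time points / conditions), one per feature.
    values : (n, f) float array
        Normalized expression values; all finite.
    """

    gene_ids: tuple[str, ...]
    feature_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(
            self, "feature_labels", tuple(str(c) for c in self.feature_labels)
        )
        object.__setattr__(self, "values", vals)
        n, f = vals.shape if vals.ndim == 2 else (0, 0)
        if vals.ndim != 2 or n < 2 or f < 2:
            raise ShapeError(
                f"expression matrix must be 2-D with n >= 2 genes and f >= 2 "
                f"features, got shape {vals.shape}"
            )
        if len(self.gene_ids) != n:
            raise ShapeError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.feature_labels) != f:
            raise ShapeError(f"{len(self.feature_labels)} labels for {f} columns")
        if not np.all(np.isfinite(vals)):
            raise ParseError("expression values must all be finite")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise UniquenessError(f"duplicate gene identifier {g!r}")
            seen.add(g)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_labels))
        df.insert(0, "gene_id", list(self.gene_ids))
        return df


def load_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    id_column: int = 0,
) -> ExpressionMatrix:
    """Read a delimited expression table with a header row.

    Raises
    ------
    FormatError
        Ragged rows (message names the offending line number).
    UniquenessError
        Two rows share an identifier.
    ParseError
        A feature cell does not parse as a real number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        width = len(header)
        if id_column < 0 or id_column >= width:
            raise FormatError(
                f"{path}: id_column {id_column} out of range for {width} columns"
            )
        feature_labels = [h for j, h in enumerate(header) if j != id_column]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:  # tolerate trailing blank line
                continue
            if len(rec) != width:
                raise FormatError(
                    f"{path}: line {lineno} has {len(rec)} fields, expected {width}"
                )
            gene_ids.append(rec[id_column])
            row = []
            for j, cell in enumerate(rec):
                if j == id_column:
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}, column {header[j]!r}: "
                        f"cannot parse {cell!r} as a number"
                    ) from None
            rows.append(row)
    return ExpressionMatrix(tuple(gene_ids), tuple(feature_labels), np.array(rows))


def save_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    delimiter: str = "\t",
    id_label: str = "gene_id",
) -> None:
    """Write a matrix back to delimited text with full (17 sig. digit) precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow([id_label, *matrix.feature_labels])
        for gid, row in zip(matrix.gene_ids, matrix.values):
            writer.writerow([gid, *(format(v, ".17g") for v in row)])


def export_cluster_heatmap(
    matrix: ExpressionMatrix,
    labels: Sequence[int],
    path: str | Path | None = None,
    delimiter: str = "\t",
    png_path: str | Path | None = None,
) -> pd.DataFrame:
    """Reorder rows so clusters are contiguous (Eisen-plot ordering).

    Clusters appear in ascending label order; within a cluster the input row
    order is preserved.  The returned table carries a ``cluster`` column; if
    *path* is given it is also written as delimited text, and *png_path*
    renders a simple raster heatmap.
    """
    labels = np.asarray(labels)
    if labels.shape != (matrix.n_genes,):
        raise ShapeError(
            f"labels length {labels.shape} does not match n={matrix.n_genes}"
        )
    if labels.size and (labels.min() < 0):
        raise IndexError(f"cluster label {labels.min()} out of range")
    order = np.argsort(labels, kind="stable")
    df = matrix.to_frame().iloc[order].reset_index(drop=True)
    df.insert(1, "cluster", labels[order])
    if path is not None:
        df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    if png_path is not None:
        _render_heatmap(df, matrix.feature_labels, png_path)
    return df


def _render_heatmap(df: pd.DataFrame, feature_labels, png_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = df[list(feature_labels)].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 8))
    vmax = np.abs(data).max() or 1.0
    ax.imshow(data, aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    # horizontal separators between cluster blocks
    bounds = np.flatnonzero(np.diff(df["cluster"].to_numpy())) + 0.5
    for y in bounds:
        ax.axhline(y, color="black", lw=0.8)
    ax.set_xticks(range(len(feature_labels)), feature_labels, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("condition / time point")
    ax.set_ylabel("genes (cluster-ordered)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
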