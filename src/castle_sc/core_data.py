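"""Labeled gene-expression datasets: I/O, log-scale normalization, summaries.

The in-memory container is :class:`GeneExpressionDataset`: a dense
cells x genes matrix of log2(count+1) expression values, with gene and
cell identifiers and one cell-type label per cell. Readers accept
delimited text (CSV/TSV, identifiers in the first row/column) and
MatrixMarket coordinate files with ``genes.tsv`` / ``barcodes.tsv``
sidecars; all readers accept gzip-compressed files.

Descriptive statistics (class counts, imbalance ratio, sparsity, and
the cosine similarity between class-count vectors of two datasets) are
computed on the matrix as loaded, before any gene filtering.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import InputError

__all__ = [
    "GeneExpressionDataset",
    "DatasetSummary",
    "LogScaleReport",
    "read_dataset",
    "write_dataset",
    "to_log_scale",
    "summarize",
    "class_distribution_cosine",
    "source_usable_mask",
    "DEFAULT_EXCLUDED_LABELS",
    "is_excluded_label",
    "RAW_SCALE_MAX",
]

#: Labels excluded when a dataset is used as a training source. Matching is
#: case-insensitive; any label containing "contaminated" is also excluded.
DEFAULT_EXCLUDED_LABELS = frozenset({"unknown", "not applicable", "unclassified"})

#: A matrix whose maximum exceeds this is judged to be on a raw-count scale
#: (log2 of any realistic count+1 stays well below it) and is log-transformed.
RAW_SCALE_MAX = 50.0


@dataclass
class GeneExpressionDataset:
    """A cells x genes expression matrix with identifiers and cell labels.

    Parameters
    ----------
    matrix
        Dense float array, cells as rows, genes as columns. Values must be
        finite and non-negative (log2(count+1) units after normalization).
    gene_ids
        Column identifiers; must be unique.
    cell_ids
        Row identifiers, one per cell.
    labels
        One cell-type label per cell. May include annotations such as
        "unknown" or "contaminated"; those cells are excluded from
        training sources but retained in targets.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise InputError(f"expression matrix must be 2-D, got {self.matrix.ndim}-D")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        n_cells, n_genes = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise InputError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells or len(self.labels) != n_cells:
            raise InputError(
                f"matrix has {n_cells} cells but {len(self.cell_ids)} cell ids "
                f"and {len(self.labels)} labels"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise InputError(f"duplicate gene identifiers: {sorted(dupes)[:10]}")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("expression matrix contains non-finite values")
        if (self.matrix < 0).any():
            raise InputError("expression matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "GeneExpressionDataset":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise InputError(f"genes not in dataset: {missing[:10]}")
        cols = [index[g] for g in gene_ids]
        return GeneExpressionDataset(
            self.matrix[:, cols], list(gene_ids), list(self.cell_ids), list(self.labels)
        )

    def subset_cells(self, mask: np.ndarray) -> "GeneExpressionDataset":
        """Return a copy restricted to the cells selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return GeneExpressionDataset(
            self.matrix[mask],
            list(self.gene_ids),
            [c for c, m in zip(self.cell_ids, mask) if m],
            [l for l, m in zip(self.labels, mask) if m],
        )


@dataclass
class DatasetSummary:
    """Descriptive statistics of a labeled dataset before any filtering."""

    n_cells: int
    n_genes: int
    class_counts: dict[str, int]
    imbalance_ratio: float  # majority count / minority count, >= 1
    sparsity_pct: float  # percentage of zero entries, in [0, 100]

    def rounded(self) -> "DatasetSummary":
        """Copy with the ratio and sparsity rounded to 1 decimal, as reported."""
        return DatasetSummary(
            self.n_cells,
            self.n_genes,
            dict(self.class_counts),
            round(self.imbalance_ratio, 1),
            round(self.sparsity_pct, 1),
        )


class LogScaleReport(NamedTuple):
    applied: bool
    reason: str


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _open_maybe_gzip(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_labels(labels_path: str) -> pd.DataFrame:
    """Read a 1- or 2-column (cell_id, label) delimited file."""
    sep = "\t" if ".tsv" in os.path.basename(str(labels_path)) else ","
    df = pd.read_csv(labels_path, sep=sep, header=None, dtype=str)
    # tolerate a header row of the form "cell_id,label"
    first = [str(v).lower() for v in df.iloc[0]]
    if first[-1] in {"label", "labels", "cell_type", "celltype"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] not in (1, 2):
        raise InputError(
            f"labels file must have 1 or 2 columns, found {df.shape[1]}"
        )
    return df


def read_dataset(
    matrix_path: str,
    format: str,
    labels_path: str,
    orientation: str = "cells_as_rows",
) -> GeneExpressionDataset:
    """Load an expression matrix and its per-cell labels.

    Parameters
    ----------
    matrix_path
        CSV/TSV file with identifiers in the first row and column, or a
        MatrixMarket coordinate file. For MTX, ``genes.tsv`` and
        ``barcodes.tsv`` sidecars are looked up next to the matrix file.
    format
        One of ``csv``, ``tsv``, ``mtx``.
    labels_path
        Delimited file with one label per cell: either two columns
        (cell_id, label), matched by cell id, or a single label column
        matched positionally.
    orientation
        ``cells_as_rows`` or ``genes_as_rows`` describing the on-disk
        layout; the returned dataset is always cells x genes.
    """
    if format not in {"csv", "tsv", "mtx"}:
        raise InputError(f"unknown format {format!r}; expected csv, tsv or mtx")
    if orientation not in {"cells_as_rows", "genes_as_rows"}:
        raise InputError(f"unknown orientation {orientation!r}")

    if format in {"csv", "tsv"}:
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        matrix = df.to_numpy(dtype=np.float64)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        with _open_maybe_gzip(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
        matrix = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        base = os.path.dirname(os.path.abspath(str(matrix_path)))
        genes_file = _find_sidecar(base, "genes.tsv")
        barcodes_file = _find_sidecar(base, "barcodes.tsv")
        genes = pd.read_csv(genes_file, sep="\t", header=None, dtype=str)[0].tolist()
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None, dtype=str)[0].tolist()
        if orientation == "genes_as_rows":
            row_ids, col_ids = genes, barcodes
        else:
            row_ids, col_ids = barcodes, genes
        if matrix.shape != (len(row_ids), len(col_ids)):
            raise InputError(
                f"MTX shape {matrix.shape} does not match sidecars "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )

    if orientation == "genes_as_rows":
        matrix = matrix.T
        gene_ids, cell_ids = row_ids, col_ids
    else:
        gene_ids, cell_ids = col_ids, row_ids

    ldf = _read_labels(labels_path)
    n_cells = matrix.shape[0]
    if len(ldf) != n_cells:
        raise InputError(
            f"labels file has {len(ldf)} entries but the matrix has {n_cells} cells"
        )
    if ldf.shape[1] == 2:
        mapping = dict(zip(ldf.iloc[:, 0], ldf.iloc[:, 1]))
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise InputError(f"labels missing for cells: {missing[:10]}")
        labels = [mapping[c] for c in cell_ids]
    else:
        labels = ldf.iloc[:, 0].tolist()

    return GeneExpressionDataset(matrix, gene_ids, cell_ids, labels)


def _find_sidecar(base: str, name: str) -> str:
    for cand in (os.path.join(base, name), os.path.join(base, name + ".gz")):
        if os.path.exists(cand):
            return cand
    raise InputError(f"MTX sidecar {name} not found in {base}")


def write_dataset(
    ds: GeneExpressionDataset,
    matrix_path: str,
    format: str,
    labels_path: str,
    orientation: str = "cells_as_rows",
) -> None:
    """Write a dataset in a layout :func:`read_dataset` round-trips."""
    if format in {"csv", "tsv"}:
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_ids)
        if orientation == "genes_as_rows":
            df = df.T
        df.to_csv(matrix_path, sep=sep)
    elif format == "mtx":
        mat = scipy.sparse.coo_matrix(
            ds.matrix.T if orientation == "genes_as_rows" else ds.matrix
        )
        scipy.io.mmwrite(os.fspath(matrix_path), mat)
        base = os.path.dirname(os.path.abspath(str(matrix_path)))
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(base, "genes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(
            os.path.join(base, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    else:
        raise InputError(f"unknown format {format!r}")
    pd.DataFrame({"cell_id": ds.cell_ids, "label": ds.labels}).to_csv(
        labels_path, index=False, header=False,
        sep="\t" if ".tsv" in os.path.basename(str(labels_path)) else ","
    )


def to_log_scale(
    ds: GeneExpressionDataset, force: bool = False
) -> tuple[GeneExpressionDataset, LogScaleReport]:
    """Convert a raw-count matrix to log2(x+1); leave log-scale data alone.

    A matrix is judged raw when its maximum value exceeds ``RAW_SCALE_MAX``;
    ``force=True`` applies the transform unconditionally.
    """
    if (ds.matrix < 0).any():
        raise InputError("negative values: neither raw counts nor log scale")
    mx = float(ds.matrix.max()) if ds.matrix.size else 0.0
    if force or mx > RAW_SCALE_MAX:
        out = GeneExpressionDataset(
            np.log2(ds.matrix + 1.0), list(ds.gene_ids), list(ds.cell_ids), list(ds.labels)
        )
        reason = "forced" if force and mx <= RAW_SCALE_MAX else (
            f"max value {mx:g} > {RAW_SCALE_MAX:g}, judged raw counts"
        )
        return out, LogScaleReport(True, f"applied log2(x+1): {reason}")
    return ds, LogScaleReport(
        False, f"already log-scale (max value {mx:g} <= {RAW_SCALE_MAX:g})"
    )


def summarize(ds: GeneExpressionDataset) -> DatasetSummary:
    """Class counts, imbalance ratio and sparsity of a dataset as loaded."""
    if ds.n_cells == 0 or ds.n_genes == 0:
        raise InputError("cannot summarize an empty dataset")
    counts: dict[str, int] = {}
    for l in ds.labels:
        counts[l] = counts.get(l, 0) + 1
    nonzero_counts = [c for c in counts.values() if c > 0]
    imbalance = max(nonzero_counts) / min(nonzero_counts)
    sparsity = 100.0 * float(np.count_nonzero(ds.matrix == 0)) / ds.matrix.size
    return DatasetSummary(ds.n_cells, ds.n_genes, counts, imbalance, sparsity)


def class_distribution_cosine(counts_a, counts_b) -> float:
    """Cosine similarity between two aligned per-class count vectors."""
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InputError(
            f"count vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InputError("cosine similarity undefined for a zero count vector")
    return float(a @ b / (na * nb))


def is_excluded_label(label: str, excluded=DEFAULT_EXCLUDED_LABELS) -> bool:
    """True for annotations that mark a cell as unusable training ground truth."""
    low = str(label).strip().lower()
    return low in excluded or "contaminated" in low


def source_usable_mask(labels, excluded=DEFAULT_EXCLUDED_LABELS) -> np.ndarray:
    """Boolean mask of cells usable when the dataset serves as a source.

    Cells labeled unknown/not applicable/unclassified, or with any label
    containing "contaminated", are dropped from sources but are kept when
    the same dataset is evaluated as a target.
    """
    return np.array([not is_excluded_label(l, excluded) for l in labels], dtype=bool)
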