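"""Expression-matrix container and on-disk formats.

The central object is :class:`ExpressionDataset`, a cells × genes non-negative
matrix with gene/cell identifiers and optional per-cell type and batch labels.
Three on-disk formats are supported: Matrix Market with ``genes.tsv`` /
``barcodes.tsv`` sidecars, dense delimited text (header = gene IDs, first
column = cell IDs), and the h5ad annotated-matrix container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    DuplicateIDError,
    NegativeValueError,
    UnknownCellIDError,
)

logger = logging.getLogger(__name__)

FORMATS = ("mtx", "dense", "h5ad")


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise DuplicateIDError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionDataset:
    """Cells × genes expression matrix with identifiers and optional labels.

    Parameters
    ----------
    matrix
        Non-negative, finite ``(n_cells, n_genes)`` array or sparse matrix.
    gene_ids, cell_ids
        Unique, ordered identifiers matching the matrix dimensions.
    labels
        Optional per-cell cell-type strings (length ``n_cells``).
    batch
        Optional per-cell batch strings (length ``n_cells``).
    """

    matrix: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None
    batch: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(self.matrix)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.ndim != 2:
                raise ValueError("matrix must be 2-dimensional")
        n, m = self.matrix.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.gene_ids):
            raise ValueError(
                f"matrix has {m} columns but {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.matrix.data if sp.issparse(self.matrix) else self.matrix
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise NegativeValueError(
                "expression matrix must be non-negative and finite"
            )
        for name, vec in (("labels", self.labels), ("batch", self.batch)):
            if vec is not None and len(vec) != n:
                raise ValueError(f"{name} must have one entry per cell")
        if self.labels is not None:
            self.labels = [str(v) for v in self.labels]
        if self.batch is not None:
            self.batch = [str(v) for v in self.batch]

    # -- views ------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        """Matrix as a dense float array."""
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=float)
        return self.matrix

    def subset_cells(self, idx: np.ndarray) -> "ExpressionDataset":
        """Row subset (cells), preserving labels and batch."""
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            batch=None if self.batch is None else [self.batch[i] for i in idx],
        )

    def subset_genes(self, gene_list: list[str]) -> "ExpressionDataset":
        """Column subset in the given gene order; unknown genes error."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_list if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        cols = np.array([index[g] for g in gene_list], dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[:, cols],
            gene_ids=list(gene_list),
            cell_ids=list(self.cell_ids),
            labels=None if self.labels is None else list(self.labels),
            batch=None if self.batch is None else list(self.batch),
        )

    def with_matrix(self, matrix) -> "ExpressionDataset":
        return replace(self, matrix=matrix)


@dataclass(frozen=True)
class LabelCodebook:
    """Deterministic (lexicographic) ordering of the t cell-type labels."""

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("a codebook needs at least 2 cell types")
        if list(self.types) != sorted(set(self.types)):
            raise ValueError("types must be unique and lexicographically sorted")

    @classmethod
    def from_labels(cls, labels: list[str]) -> "LabelCodebook":
        return cls(tuple(sorted(set(labels))))

    @property
    def t(self) -> int:
        return len(self.types)

    def encode(self, labels: list[str]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.types)}
        try:
            return np.array([index[l] for l in labels], dtype=int)
        except KeyError as e:
            raise KeyError(f"label {e.args[0]!r} not in codebook") from None

    def decode(self, codes: np.ndarray) -> list[str]:
        return [self.types[int(c)] for c in codes]


# -- readers ---------------------------------------------------------------


def _read_labels(labels_path, cell_ids: list[str]) -> tuple[list[str], list[str] | None]:
    """2-column (cell_id, cell_type) or 3-column (+ batch) TSV, with or
    without a header line."""
    df = pd.read_csv(labels_path, sep="\t", header=None, dtype=str, comment="#")
    first = df.iloc[0].tolist()
    if first[0] in ("cell_id", "barcode", "cell"):
        df = df.iloc[1:].reset_index(drop=True)
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    unknown = set(df.iloc[:, 0]) - set(cell_ids)
    if unknown:
        raise UnknownCellIDError(
            f"label table references unknown cell id(s): {sorted(unknown)[:5]}"
        )
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise UnknownCellIDError(
            f"label table is missing cell id(s): {missing[:5]}"
        )
    labels = [mapping[c] for c in cell_ids]
    batch = None
    if df.shape[1] >= 3:
        bmap = dict(zip(df.iloc[:, 0], df.iloc[:, 2]))
        batch = [bmap[c] for c in cell_ids]
    return labels, batch


def read_dataset(
    path: str | Path,
    format: str | None = None,
    labels_path: str | Path | None = None,
    genes_in_rows: bool = False,
) -> ExpressionDataset:
    """Read an expression matrix into a validated :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        For ``mtx``: the ``.mtx`` file (sidecars ``genes.tsv`` and
        ``barcodes.tsv`` expected next to it); for ``dense``: a CSV/TSV with a
        header row of gene IDs and a first column of cell IDs; for ``h5ad``:
        an AnnData container.
    format
        One of ``{"mtx", "dense", "h5ad"}``; inferred from the suffix when
        omitted.
    labels_path
        Optional TSV mapping every cell ID to a cell type (third column, if
        present, is the batch).
    genes_in_rows
        Dense input only: set when the file stores genes as rows.  Matrix
        Market input follows the 10x convention (genes as rows) and is
        transposed automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".h5ad": "h5ad"}.get(path.suffix, "dense")
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")

    if format == "mtx":
        mat = sp.csr_matrix(scipy.io.mmread(path))
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None, dtype=str)
        cells = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None, dtype=str)
        gene_ids = genes.iloc[:, 0].tolist()
        cell_ids = cells.iloc[:, 0].tolist()
        # 10x convention stores genes × cells
        if mat.shape == (len(gene_ids), len(cell_ids)):
            mat = mat.T.tocsr()
        elif mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither sidecar orientation"
            )
        ds = ExpressionDataset(mat, gene_ids, cell_ids)
    elif format == "dense":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if genes_in_rows:
            df = df.T
        ds = ExpressionDataset(
            df.to_numpy(dtype=float),
            gene_ids=[str(c) for c in df.columns],
            cell_ids=[str(i) for i in df.index],
        )
    else:  # h5ad
        import anndata

        adata = anndata.read_h5ad(path)
        labels = (
            adata.obs["cell_type"].astype(str).tolist()
            if "cell_type" in adata.obs
            else None
        )
        batch = (
            adata.obs["batch"].astype(str).tolist() if "batch" in adata.obs else None
        )
        ds = ExpressionDataset(
            adata.X,
            gene_ids=adata.var_names.tolist(),
            cell_ids=adata.obs_names.tolist(),
            labels=labels,
            batch=batch,
        )

    if labels_path is not None:
        labels, batch = _read_labels(labels_path, ds.cell_ids)
        ds.labels = labels
        if batch is not None:
            ds.batch = batch
    return ds


def write_dataset(ds: ExpressionDataset, path: str | Path, format: str = "mtx") -> None:
    """Write a dataset in one of the supported formats.

    ``mtx`` writes ``matrix.mtx`` + sidecars + ``labels.tsv`` into the
    directory ``path``; ``dense`` writes a single CSV/TSV; ``h5ad`` an AnnData
    container.
    """
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mat = ds.matrix if sp.issparse(ds.matrix) else sp.csr_matrix(ds.matrix)
        scipy.io.mmwrite(path / "matrix.mtx", mat.T.tocoo())  # genes × cells
        pd.Series(ds.gene_ids).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        if ds.labels is not None:
            cols = {"cell_id": ds.cell_ids, "cell_type": ds.labels}
            if ds.batch is not None:
                cols["batch"] = ds.batch
            pd.DataFrame(cols).to_csv(
                path / "labels.tsv", sep="\t", header=False, index=False
            )
    elif format == "dense":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        pd.DataFrame(ds.dense(), index=ds.cell_ids, columns=ds.gene_ids).to_csv(
            path, sep=sep
        )
    elif format == "h5ad":
        import anndata

        adata = anndata.AnnData(
            X=ds.matrix if sp.issparse(ds.matrix) else np.asarray(ds.matrix),
        )
        adata.obs_names = ds.cell_ids
        adata.var_names = ds.gene_ids
        if ds.labels is not None:
            adata.obs["cell_type"] = pd.Categorical(ds.labels)
        if ds.batch is not None:
            adata.obs["batch"] = pd.Categorical(ds.batch)
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")
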