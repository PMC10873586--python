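"""Per-cell total-count normalization and gene-space alignment.

Normalization rescales every cell to a fixed total (default 1e4) and
optionally applies log1p, mirroring the standard single-cell recipe.  Training
and test data are always processed independently — no statistic is shared
between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datasets import ExpressionDataset
from .errors import AllZeroCellError, DisjointGeneSpacesError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessSettings:
    """Settings for :func:`normalize_cells`.

    target_scale
        Every cell's counts are rescaled to sum to this value (default 1e4,
        the conventional counts-per-ten-thousand target).
    log_transform
        Apply ``log(1 + x)`` after rescaling.
    drop_zero_cells
        Drop all-zero cells with a warning instead of raising.
    apply_gene_filter / min_cells_per_gene
        Optionally remove genes detected in fewer than ``min_cells_per_gene``
        cells before normalizing.
    """

    target_scale: float = 1e4
    log_transform: bool = True
    drop_zero_cells: bool = False
    apply_gene_filter: bool = False
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.target_scale <= 0:
            raise ValueError("target_scale must be positive")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be non-negative")


def normalize_cells(
    data: ExpressionDataset, settings: PreprocessSettings | None = None
) -> ExpressionDataset:
    """Total-count normalize each cell, optionally followed by log1p.

    Each entry becomes ``x / sum(cell) * target_scale``; before the log
    transform every cell's row sum equals ``target_scale`` exactly.
    """
    settings = settings or PreprocessSettings()
    ds = data

    if settings.apply_gene_filter:
        mat = ds.matrix
        detected = (
            np.asarray((mat > 0).sum(axis=0)).ravel()
            if sp.issparse(mat)
            else (mat > 0).sum(axis=0)
        )
        keep = detected >= settings.min_cells_per_gene
        if not keep.all():
            logger.warning("gene filter removed %d genes", int((~keep).sum()))
            ds = ds.subset_genes([g for g, k in zip(ds.gene_ids, keep) if k])

    mat = ds.matrix
    totals = np.asarray(mat.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = [ds.cell_ids[i] for i in np.flatnonzero(zero)]
        if not settings.drop_zero_cells:
            raise AllZeroCellError(
                f"cell(s) with zero total counts: {bad[:5]}; "
                "enable drop_zero_cells to remove them"
            )
        logger.warning("dropping %d all-zero cell(s): %s", len(bad), bad[:5])
        ds = ds.subset_cells(np.flatnonzero(~zero))
        mat = ds.matrix
        totals = totals[~zero]

    scale = settings.target_scale / totals
    if sp.issparse(mat):
        out = sp.diags(scale) @ mat
        if settings.log_transform:
            out = out.tocsr()
            out.data = np.log1p(out.data)
    else:
        out = mat * scale[:, None]
        if settings.log_transform:
            out = np.log1p(out)
    return ds.with_matrix(out)


def align_genes(
    train_genes: list[str], test: ExpressionDataset, fill: float = 0.0
) -> ExpressionDataset:
    """Project a test dataset onto the training gene space.

    Columns are reordered to ``train_genes``; genes absent from the test data
    are filled with ``fill`` (and counted in a warning); extra test genes are
    dropped.  Raises :class:`DisjointGeneSpacesError` when no gene is shared.
    """
    if not train_genes:
        raise ValueError("train_genes must be non-empty")
    index = {g: j for j, g in enumerate(test.gene_ids)}
    shared = [g for g in train_genes if g in index]
    if not shared:
        raise DisjointGeneSpacesError(
            "disjoint gene spaces: no training gene found in test data"
        )
    n_missing = len(train_genes) - len(shared)
    if n_missing:
        logger.warning(
            "%d gene(s) absent from test data imputed with %g", n_missing, fill
        )
    dense = test.dense()
    out = np.full((test.n_cells, len(train_genes)), float(fill))
    for j, g in enumerate(train_genes):
        if g in index:
            out[:, j] = dense[:, index[g]]
    return ExpressionDataset(
        matrix=out,
        gene_ids=list(train_genes),
        cell_ids=list(test.cell_ids),
        labels=None if test.labels is None else list(test.labels),
        batch=None if test.batch is None else list(test.batch),
    )
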