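"""One-vs-rest χ² gene selection.

For each cell type the t-class problem is recast as a binary one (that type
vs. the rest) and genes are ranked by a frequency-based χ² statistic over
class-wise expression sums.  The top-k genes per type form that type's
signature; signatures may overlap across types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import ExpressionDataset, LabelCodebook
from .errors import DegenerateSplitError, NegativeValueError

DEFAULT_GENES_PER_TYPE = 300


@dataclass
class SignatureSet:
    """Per-type ordered gene signatures with their χ² scores.

    ``per_type[C]`` lists the selected gene IDs for type ``C`` in descending
    χ² order (ties broken by gene ID); ``scores[C]`` holds the full per-gene
    score vector over the training gene space, for audit.
    """

    per_type: dict[str, list[str]]
    k: int
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def types(self) -> list[str]:
        return sorted(self.per_type)

    def union_genes(self) -> list[str]:
        """All signature genes, deduplicated, in codebook-then-rank order."""
        seen: dict[str, None] = {}
        for c in self.types:
            for g in self.per_type[c]:
                seen.setdefault(g)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cell_type, rank, gene_id, chi2_score)."""
        rows = []
        for c in self.types:
            gidx = {g: j for j, g in enumerate(self.gene_ids)}
            for rank, g in enumerate(self.per_type[c], start=1):
                score = float(self.scores[c][gidx[g]]) if c in self.scores else np.nan
                rows.append((c, rank, g, score))
        return pd.DataFrame(rows, columns=["cell_type", "rank", "gene_id", "chi2_score"])


def binarize_labels(labels: list[str], target: str) -> np.ndarray:
    """One-vs-rest indicator: 1 where label equals ``target``, else 0."""
    y = np.array([1 if l == target else 0 for l in labels], dtype=int)
    if y.sum() == 0:
        raise DegenerateSplitError(f"target type {target!r} absent from labels")
    if y.sum() == len(y):
        raise DegenerateSplitError(
            f"degenerate split: every cell has type {target!r}"
        )
    return y


def chi2_scores(matrix, y: np.ndarray) -> np.ndarray:
    """Frequency-based per-gene χ² statistic for a binary split.

    For gene j with class-wise observed sums ``O_c = Σ_{i: y_i=c} x_ij`` and
    class sizes ``N_c``, the expected sums under independence are
    ``E_c = T_j · N_c / n`` with ``T_j = Σ_i x_ij``, and

        score_j = Σ_c (O_c − E_c)² / E_c.

    Genes with zero total expression score 0 by convention.
    """
    y = np.asarray(y)
    if y.min() == y.max():
        raise DegenerateSplitError("y must contain both classes")
    if sp.issparse(matrix):
        data = matrix.data
        if data.size and data.min() < 0:
            raise NegativeValueError("χ² requires non-negative features")
        o1 = np.asarray(matrix[y == 1].sum(axis=0)).ravel()
        total = np.asarray(matrix.sum(axis=0)).ravel()
    else:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.size and matrix.min() < 0:
            raise NegativeValueError("χ² requires non-negative features")
        o1 = matrix[y == 1].sum(axis=0)
        total = matrix.sum(axis=0)
    n = len(y)
    n1 = int(y.sum())
    e1 = total * (n1 / n)
    e0 = total * ((n - n1) / n)
    o0 = total - o1
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    score[total == 0] = 0.0
    return score


def _top_k(scores: np.ndarray, gene_ids: list[str], k: int) -> list[str]:
    # descending score, ties broken by lexicographic gene ID
    order = sorted(range(len(gene_ids)), key=lambda j: (-scores[j], gene_ids[j]))
    return [gene_ids[j] for j in order[: min(k, len(gene_ids))]]


def select_signatures(
    data: ExpressionDataset, k: int = DEFAULT_GENES_PER_TYPE
) -> SignatureSet:
    """Select the top-k genes per cell type by one-vs-rest χ² score.

    The input is expected to be normalized already (selection operates on the
    same values the classifiers will see).  Deterministic under fixed input:
    ties in the ranking are broken by gene ID.
    """
    if data.labels is None:
        raise ValueError("select_signatures requires a labeled dataset")
    if k < 1:
        raise ValueError("k must be >= 1")
    codebook = LabelCodebook.from_labels(data.labels)
    per_type: dict[str, list[str]] = {}
    scores: dict[str, np.ndarray] = {}
    for c in codebook.types:
        y = binarize_labels(data.labels, c)
        s = chi2_scores(data.matrix, y)
        scores[c] = s
        per_type[c] = _top_k(s, data.gene_ids, k)
    return SignatureSet(per_type=per_type, k=k, scores=scores, gene_ids=list(data.gene_ids))
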