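"""Synthetic labeled scRNA-seq datasets with planted cell-type structure.

Counts are drawn from a negative binomial (gamma–Poisson mixture) with mean
``base_mean`` and over-dispersion ``dispersion`` (variance = μ + φ·μ²).  Each
cell type gets ``markers_per_type`` disjoint marker genes whose mean is
up-shifted by ``exp(log_fold_change)`` in that type.  Optional per-batch
per-gene multiplicative log-normal factors emulate batch effects.  Everything
is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ExpressionDataset


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a well-separated three-type population: 200 cells per
    type, 2000 genes of which 20 per type are markers with a log-fold-change
    of 2 over a base mean of 5, moderate over-dispersion (φ = 0.3), one batch.
    """

    n_types: int = 3
    cells_per_type: tuple[int, ...] = (200, 200, 200)
    n_genes: int = 2000
    markers_per_type: int = 20
    log_fold_change: float = 2.0
    base_mean: float = 5.0
    dispersion: float = 0.3
    batch_effect_sd: float = 0.0
    n_batches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type must have one entry per type")
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("cells_per_type entries must be positive")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("n_types * markers_per_type must not exceed n_genes")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if self.log_fold_change < 0:
            raise ValueError("log_fold_change must be non-negative")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw with var = μ + φ·μ² (shape 1/φ, scale φ·μ)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, dict[str, list[str]]]:
    """Generate a labeled dataset plus the planted marker map.

    Returns ``(dataset, markers)`` where ``markers[type]`` lists the gene IDs
    whose mean was multiplied by ``exp(log_fold_change)`` in that type's
    cells.  Cells are assigned to batches round-robin; batch effects are
    per-batch per-gene log-normal factors with sd ``batch_effect_sd``.
    """
    rng = np.random.default_rng(config.seed)
    types = [f"type{k}" for k in range(config.n_types)]
    gene_ids = [f"g{j:05d}" for j in range(config.n_genes)]
    markers = {
        t: gene_ids[k * config.markers_per_type : (k + 1) * config.markers_per_type]
        for k, t in enumerate(types)
    }

    labels = [t for t, n in zip(types, config.cells_per_type) for _ in range(n)]
    n_cells = len(labels)
    batch = [f"batch{i % config.n_batches}" for i in range(n_cells)]

    # per-type mean profile over genes
    profiles = np.full((config.n_types, config.n_genes), config.base_mean)
    for k in range(config.n_types):
        lo, hi = k * config.markers_per_type, (k + 1) * config.markers_per_type
        profiles[k, lo:hi] *= np.exp(config.log_fold_change)

    # per-batch per-gene multiplicative factors
    if config.batch_effect_sd > 0:
        factors = np.exp(
            rng.normal(0.0, config.batch_effect_sd, size=(config.n_batches, config.n_genes))
        )
    else:
        factors = np.ones((config.n_batches, config.n_genes))

    type_index = {t: k for k, t in enumerate(types)}
    mean = np.empty((n_cells, config.n_genes))
    for i in range(n_cells):
        mean[i] = profiles[type_index[labels[i]]] * factors[i % config.n_batches]
    counts = _nb_draw(rng, mean, config.dispersion).astype(float)

    ds = ExpressionDataset(
        matrix=counts,
        gene_ids=gene_ids,
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        labels=labels,
        batch=batch if config.n_batches > 1 else None,
    )
    return ds, markers


PAIR_MODES = ("batch-shift", "label-subset")


def simulate_pair(
    config: SimulationConfig, mode: str = "batch-shift"
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Matched (train, test) pair for cross-dataset protocols.

    ``batch-shift``: both sets share cell types but carry independent batch
    factors (sd ``batch_effect_sd``); with sd = 0 the pair is exchangeable.
    ``label-subset``: the test set carries one extra cell type absent from
    training, emulating a reference that does not cover the query tissue.
    """
    if mode not in PAIR_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {PAIR_MODES}")
    if mode == "batch-shift":
        two_batch = replace(config, n_batches=2)
        ds, _ = simulate_dataset(two_batch)
        b = np.array(ds.batch)
        train = ds.subset_cells(np.flatnonzero(b == "batch0"))
        test = ds.subset_cells(np.flatnonzero(b == "batch1"))
        return train, test

    # label-subset: simulate with one extra type, withhold it from training
    extra = replace(
        config,
        n_types=config.n_types + 1,
        cells_per_type=tuple(config.cells_per_type) + (config.cells_per_type[-1],),
    )
    ds, _ = simulate_dataset(extra)
    labels = np.array(ds.labels)
    extra_type = f"type{config.n_types}"
    rng = np.random.default_rng(config.seed + 1)
    is_extra = labels == extra_type
    # split the shared types in half; extra type goes entirely to test
    test_mask = is_extra.copy()
    for t in sorted(set(labels) - {extra_type}):
        idx = np.flatnonzero(labels == t)
        half = rng.choice(idx, size=len(idx) // 2, replace=False)
        test_mask[half] = True
    train = ds.subset_cells(np.flatnonzero(~test_mask))
    test = ds.subset_cells(np.flatnonzero(test_mask))
    return train, test
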