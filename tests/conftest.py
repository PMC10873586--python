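import numpy as np
import pytest

import cellstack as cs


@pytest.fixture(scope="session")
def sim_small():
    """Well-separated 3-type dataset, small enough for fast model fits."""
    cfg = cs.SimulationConfig(
        n_types=3,
        cells_per_type=(40, 40, 40),
        n_genes=200,
        markers_per_type=10,
        log_fold_change=2.0,
        base_mean=5.0,
        seed=7,
    )
    ds, markers = cs.simulate_dataset(cfg)
    return ds, markers, cfg


@pytest.fixture(scope="session")
def fast_config():
    """Logistic-regression-only stacking config for protocol tests."""
    return {"k": 20, "learners": cs.parse_learners("lr"), "folds": 3}


@pytest.fixture
def tiny_dense():
    """3 cells x 4 genes with hand-checkable values."""
    return cs.ExpressionDataset(
        matrix=np.array([[1.0, 2.0, 3.0, 4.0],
                         [0.0, 1.0, 0.0, 1.0],
                         [5.0, 0.0, 0.0, 5.0]]),
        gene_ids=["gA", "gB", "gC", "gD"],
        cell_ids=["c1", "c2", "c3"],
        labels=["T1", "T2", "T1"],
    )


def brute_force_chi2(matrix, y):
    """Independent per-gene chi-square over class-wise observed/expected sums."""
    matrix = np.asarray(matrix, dtype=float)
    y = np.asarray(y)
    n = len(y)
    scores = np.zeros(matrix.shape[1])
    for j in range(matrix.shape[1]):
        total = matrix[:, j].sum()
        if total == 0:
            continue
        s = 0.0
        for c in (0, 1):
            observed = matrix[y == c, j].sum()
            expected = total * (y == c).sum() / n
            s += (observed - expected) ** 2 / expected
        scores[j] = s
    return scores


def brute_force_metrics(true_labels, pred_labels):
    """Counting-based accuracy / per-class F1 / macro / median."""
    true_labels, pred_labels = list(true_labels), list(pred_labels)
    n = len(true_labels)
    acc = sum(t == p for t, p in zip(true_labels, pred_labels)) / n
    per_class = {}
    for c in sorted(set(true_labels)):
        tp = sum(t == c and p == c for t, p in zip(true_labels, pred_labels))
        fp = sum(t != c and p == c for t, p in zip(true_labels, pred_labels))
        fn = sum(t == c and p != c for t, p in zip(true_labels, pred_labels))
        denom = 2 * tp + fp + fn
        per_class[c] = 2 * tp / denom if denom else 0.0
    vals = sorted(per_class.values())
    k = len(vals)
    median = vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
    return acc, per_class, sum(vals) / k, median
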