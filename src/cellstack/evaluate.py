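"""Metrics and evaluation protocols.

Metrics: accuracy, per-class F1 (computed over the classes present in the
test truth), macro F1 (unweighted mean) and median F1.  Protocols: stratified
k-fold cross-validation within one dataset (intra), train-on-one /
test-on-another (inter, cross-batch, cross-species), and the repeated
class-balanced down-sampling protocol for imbalanced training sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

from .datasets import ExpressionDataset
from .errors import ClassTooSmallError, EmptyReportError
from . import stacking

logger = logging.getLogger(__name__)

PROTOCOLS = ("intra", "inter", "cross-batch", "cross-species")


@dataclass
class EvaluationReport:
    """Per-protocol evaluation summary.

    ``confusion`` is a DataFrame whose rows are the classes present in the
    truth and whose columns are all observed classes (truth ∪ predictions),
    so its entries sum to ``n_cells``.
    """

    protocol: str
    accuracy: float
    macro_f1: float
    median_f1: float
    per_class_f1: dict[str, float]
    confusion: pd.DataFrame
    n_cells: int
    repeats: int = 1
    fold_reports: list["EvaluationReport"] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("accuracy", "macro_f1", "median_f1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {v}")


def compute_metrics(
    true_labels: list[str],
    predicted_labels: list[str],
    protocol: str = "intra",
) -> EvaluationReport:
    """Accuracy, per-class/macro/median F1 and the confusion matrix.

    Per-class F1 uses 2PR/(P+R) with 0 when P+R = 0, over the classes present
    in the truth; a class predicted but never true contributes a confusion
    column only.  Median F1 is the midpoint of the two central values when the
    class count is even.
    """
    true_labels = list(map(str, true_labels))
    predicted_labels = list(map(str, predicted_labels))
    if not true_labels:
        raise ValueError("empty label vectors")
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    true_classes = sorted(set(true_labels))
    all_classes = sorted(set(true_labels) | set(predicted_labels))
    f1 = f1_score(
        true_labels, predicted_labels, labels=true_classes, average=None,
        zero_division=0,
    )
    per_class = {c: float(v) for c, v in zip(true_classes, f1)}
    conf = confusion_matrix(true_labels, predicted_labels, labels=all_classes)
    keep = [all_classes.index(c) for c in true_classes]
    conf_df = pd.DataFrame(conf[keep], index=true_classes, columns=all_classes)
    vals = np.array(list(per_class.values()))
    return EvaluationReport(
        protocol=protocol,
        accuracy=float(accuracy_score(true_labels, predicted_labels)),
        macro_f1=float(vals.mean()),
        median_f1=float(np.median(vals)),
        per_class_f1=per_class,
        confusion=conf_df,
        n_cells=len(true_labels),
    )


def _mean_reports(reports: list[EvaluationReport], protocol: str, repeats: int) -> EvaluationReport:
    """Average metrics over folds/rounds; confusion matrices are summed."""
    classes = sorted({c for r in reports for c in r.per_class_f1})
    per_class = {
        c: float(np.mean([r.per_class_f1[c] for r in reports if c in r.per_class_f1]))
        for c in classes
    }
    all_cols = sorted({c for r in reports for c in r.confusion.columns})
    conf = pd.DataFrame(0, index=classes, columns=all_cols)
    for r in reports:
        conf = conf.add(
            r.confusion.reindex(index=classes, columns=all_cols, fill_value=0),
            fill_value=0,
        )
    return EvaluationReport(
        protocol=protocol,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        median_f1=float(np.mean([r.median_f1 for r in reports])),
        per_class_f1=per_class,
        confusion=conf.astype(int),
        n_cells=int(sum(r.n_cells for r in reports)),
        repeats=repeats,
        fold_reports=reports,
    )


def stratified_kfold_cv(
    data: ExpressionDataset,
    model_config: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Intra-dataset stratified k-fold cross-validation.

    Folds preserve per-class proportions up to integer rounding.  Metrics are
    averaged over folds; per-fold reports are retained in ``fold_reports``.
    """
    if data.labels is None:
        raise ValueError("stratified_kfold_cv requires labels")
    cfg = dict(model_config or {})
    counts = pd.Series(data.labels).value_counts()
    if (counts < folds).any():
        raise ClassTooSmallError(
            f"class(es) too small for {folds}-fold CV: "
            f"{counts[counts < folds].to_dict()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    y = np.array(data.labels)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = data.subset_cells(train_idx)
        test = data.subset_cells(test_idx)
        model = stacking.fit(train, seed=seed + fold, **cfg)
        pred, _ = stacking.predict_types(model, test)
        reports.append(compute_metrics(test.labels, pred, protocol="intra"))
    return _mean_reports(reports, protocol="intra", repeats=folds)


def cross_dataset_eval(
    train: ExpressionDataset | list[ExpressionDataset],
    test: ExpressionDataset,
    model_config: dict | None = None,
    protocol: str = "inter",
    seed: int = 0,
) -> EvaluationReport:
    """Fit on training data only, evaluate on an independently processed test set.

    Multiple training datasets are pooled over the intersection of their gene
    spaces.  Metrics cover the classes present in the test truth; test-only
    classes are necessarily mispredicted and score F1 = 0.
    """
    if test.labels is None:
        raise ValueError("cross_dataset_eval requires labeled test data")
    cfg = dict(model_config or {})
    if isinstance(train, list):
        train = pool_datasets(train)
    model = stacking.fit(train, seed=seed, **cfg)
    pred, _ = stacking.predict_types(model, test)
    return compute_metrics(test.labels, pred, protocol=protocol)


def pool_datasets(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Concatenate training datasets over their shared gene space."""
    from .errors import DisjointGeneSpacesError

    if len(datasets) == 1:
        return datasets[0]
    shared = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        shared &= set(ds.gene_ids)
    if not shared:
        raise DisjointGeneSpacesError("disjoint gene spaces across training datasets")
    genes = [g for g in datasets[0].gene_ids if g in shared]
    parts = [ds.subset_genes(genes) for ds in datasets]
    return ExpressionDataset(
        matrix=np.vstack([p.dense() for p in parts]),
        gene_ids=genes,
        cell_ids=[c for p in parts for c in p.cell_ids],
        labels=[l for p in parts for l in (p.labels or [])] or None,
        batch=None,
    )


def downsample_per_class(
    data: ExpressionDataset, target: int, seed: int = 0
) -> ExpressionDataset:
    """Random per-class under-sampling to at most ``target`` cells per type.

    Classes above the target are sampled without replacement to exactly the
    target size; smaller classes are kept whole.  The original cell order is
    preserved among the kept cells.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if data.labels is None:
        raise ValueError("downsample_per_class requires labels")
    rng = np.random.default_rng(seed)
    labels = np.array(data.labels)
    keep = np.zeros(len(labels), dtype=bool)
    for c in sorted(set(labels)):
        idx = np.flatnonzero(labels == c)
        if len(idx) > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep[idx] = True
    return data.subset_cells(np.flatnonzero(keep))


def repeated_downsample_eval(
    train: ExpressionDataset,
    test: ExpressionDataset,
    target: int,
    repeats: int = 5,
    model_config: dict | None = None,
    protocol: str = "inter",
    seed: int = 0,
) -> EvaluationReport:
    """Average metrics over repeated down-sample → fit → evaluate rounds.

    Round r draws its down-sample with seed ``seed + r``; the model fit uses
    the base seed, so rounds differ only through the sampled training cells
    and the whole protocol is reproducible from one seed.
    """
    reports = []
    for r in range(repeats):
        sub = downsample_per_class(train, target, seed=seed + r)
        reports.append(
            cross_dataset_eval(sub, test, model_config, protocol=protocol, seed=seed)
        )
    return _mean_reports(reports, protocol=protocol, repeats=repeats)


# -- report I/O --------------------------------------------------------------


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write a report as JSON (``path``) plus a TSV sidecar (``path`` + .tsv).

    The JSON round-trips losslessly through :func:`read_report`.
    """
    if not report.per_class_f1:
        raise EmptyReportError("empty report: no per-class F1 entries")
    path = Path(path)
    payload = {
        "protocol": report.protocol,
        "accuracy": report.accuracy,
        "macro_f1": report.macro_f1,
        "median_f1": report.median_f1,
        "per_class_f1": report.per_class_f1,
        "confusion": {
            "rows": list(report.confusion.index),
            "columns": list(report.confusion.columns),
            "values": report.confusion.values.tolist(),
        },
        "n_cells": report.n_cells,
        "repeats": report.repeats,
    }
    path.write_text(json.dumps(payload, indent=2))
    rows = [("accuracy", report.accuracy), ("macro_f1", report.macro_f1),
            ("median_f1", report.median_f1)]
    rows += [(f"f1:{c}", v) for c, v in report.per_class_f1.items()]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False
    )


def read_report(path: str | Path) -> EvaluationReport:
    """Reload a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    conf = pd.DataFrame(
        payload["confusion"]["values"],
        index=payload["confusion"]["rows"],
        columns=payload["confusion"]["columns"],
    )
    return EvaluationReport(
        protocol=payload["protocol"],
        accuracy=payload["accuracy"],
        macro_f1=payload["macro_f1"],
        median_f1=payload["median_f1"],
        per_class_f1=payload["per_class_f1"],
        confusion=conf,
        n_cells=payload["n_cells"],
        repeats=payload["repeats"],
    )
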