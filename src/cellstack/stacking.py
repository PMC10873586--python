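"""Two-layer dynamic stacking ensemble for multi-class cell-type annotation.

First layer: for every cell type's gene signature, each base learner is
trained under a stratified out-of-fold (OOF) scheme so that every training
cell's class-probability feature comes from a model that never saw it.  The
per-(signature, learner) probability blocks are concatenated into an
n × (t·L·t) meta-feature matrix (t cell types, L base learners).  Second
layer: a multinomial logistic regression classifies cells from that matrix.
After the OOF pass, each base learner is refit on its full sub-dataset for
test-time transformation.  The model is "dynamic" in that its meta-feature
width grows with the number of cell types in the training data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datasets import ExpressionDataset, LabelCodebook
from .errors import ClassTooSmallError, ModelIOError
from .feature_selection import SignatureSet, select_signatures
from .preprocess import PreprocessSettings, align_genes, normalize_cells

logger = logging.getLogger(__name__)

# libsvm's internal Platt calibration is the seeded default for RBF-SVM
# probabilities; silence the sklearn 1.9 deprecation nudge toward the
# CalibratedClassifierCV wrapper.
warnings.filterwarnings(
    "ignore",
    message=".*`probability` parameter was deprecated.*",
    category=FutureWarning,
)

LEARNER_KINDS = (
    "rbf-svm",
    "logistic-regression",
    "random-forest",
    "gradient-boosting",
    "multilayer-perceptron",
)

_MODEL_FORMAT = "cellstack-model"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Declarative description of a first-layer probabilistic classifier.

    Hyperparameters not given here fall back to documented defaults:
    RBF-SVM with C=1 and kernel scale 1/(m·var) ("scale"), Platt-calibrated
    probabilities; L2 logistic regression with C=1 (multinomial).
    """

    kind: str
    name: str = ""
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; expected {LEARNER_KINDS}")
        if not self.name:
            object.__setattr__(self, "name", self.kind)

    def build(self, seed: int | None = None):
        """Instantiate the sklearn estimator (always probability-capable)."""
        rs = self.seed if seed is None else seed
        hp = dict(self.hyperparameters)
        if self.kind == "rbf-svm":
            est = SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                      random_state=rs, **hp)
        elif self.kind == "logistic-regression":
            est = LogisticRegression(C=1.0, max_iter=2000, **hp)
        elif self.kind == "random-forest":
            est = RandomForestClassifier(n_estimators=200, random_state=rs, **hp)
        elif self.kind == "gradient-boosting":
            est = GradientBoostingClassifier(random_state=rs, **hp)
        else:
            est = MLPClassifier(max_iter=500, random_state=rs, **hp)
        if not hasattr(est, "predict_proba"):
            raise ValueError(f"learner {self.name!r} cannot emit class probabilities")
        return est


DEFAULT_LEARNERS = (
    BaseLearnerSpec(kind="rbf-svm"),
    BaseLearnerSpec(kind="logistic-regression"),
)

_KIND_ALIASES = {
    "svm": "rbf-svm", "rbf-svm": "rbf-svm",
    "lr": "logistic-regression", "logistic-regression": "logistic-regression",
    "rf": "random-forest", "random-forest": "random-forest",
    "gbc": "gradient-boosting", "gradient-boosting": "gradient-boosting",
    "mlp": "multilayer-perceptron", "multilayer-perceptron": "multilayer-perceptron",
}


def parse_learners(names: list[str] | str) -> list[BaseLearnerSpec]:
    """Build learner specs from short names, e.g. ``"svm,lr"``."""
    if isinstance(names, str):
        names = [s.strip() for s in names.split(",") if s.strip()]
    specs = []
    for nm in names:
        if nm not in _KIND_ALIASES:
            raise ValueError(f"unknown learner {nm!r}; known: {sorted(_KIND_ALIASES)}")
        specs.append(BaseLearnerSpec(kind=_KIND_ALIASES[nm], name=nm))
    return specs


@dataclass
class MetaFeatureMatrix:
    """n × (t·L·t) matrix of stacked class-probability features.

    ``block_index[(cell_type, learner_name)]`` gives the half-open column
    range of that t-wide probability block.
    """

    values: np.ndarray
    block_index: dict[tuple[str, str], tuple[int, int]]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def build_subdataset(data: ExpressionDataset, f_k: list[str]) -> ExpressionDataset:
    """Restrict a dataset to a signature's genes, in signature order."""
    return data.subset_genes(f_k)


def _full_proba(est, X: np.ndarray, codebook: LabelCodebook) -> np.ndarray:
    """predict_proba mapped onto the full codebook column order."""
    p = est.predict_proba(X)
    out = np.zeros((X.shape[0], codebook.t))
    for col, cls in enumerate(est.classes_):
        out[:, int(cls)] = p[:, col]
    return out


def oof_transform(
    sub: ExpressionDataset,
    learner: BaseLearnerSpec,
    folds: int = 3,
    seed: int = 0,
    codebook: LabelCodebook | None = None,
    fold_record: list | None = None,
) -> np.ndarray:
    """Out-of-fold class-probability features for one (signature, learner).

    The sub-dataset is split into stratified folds; for each fold the learner
    is trained on the remaining folds and predicts class probabilities for the
    held-out cells.  Every cell therefore receives exactly one length-t
    probability vector from a model that never saw it.  ``fold_record``, when
    given, collects ``(train_idx, test_idx)`` pairs for leakage audits.
    """
    if sub.labels is None:
        raise ValueError("oof_transform requires labels")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    codebook = codebook or LabelCodebook.from_labels(sub.labels)
    y = codebook.encode(sub.labels)
    _check_class_sizes(sub.labels, folds)
    X = sub.dense()
    out = np.zeros((len(y), codebook.t))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        est = learner.build(seed=seed)
        est.fit(X[train_idx], y[train_idx])
        out[test_idx] = _full_proba(est, X[test_idx], codebook)
        if fold_record is not None:
            fold_record.append((train_idx.copy(), test_idx.copy()))
    return out


def _check_class_sizes(labels: list[str], folds: int) -> None:
    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    small = {c: n for c, n in counts.items() if n < folds}
    if small:
        raise ClassTooSmallError(
            f"class(es) too small for {folds}-fold stacking: {small}; "
            "reduce --stack-folds or drop the class"
        )


@dataclass
class StackingModel:
    """Fitted two-layer stacking artifact.

    ``base_models[(cell_type, learner_name)]`` holds the first-layer learner
    refit on the full sub-dataset for that type's signature; ``meta_model`` is
    the second-layer multinomial logistic regression over the t·L·t
    meta-feature columns.
    """

    codebook: LabelCodebook
    signatures: SignatureSet
    base_models: dict[tuple[str, str], object]
    meta_model: LogisticRegression
    learners: list[BaseLearnerSpec]
    preprocess: PreprocessSettings
    folds: int
    seed: int

    @property
    def meta_width(self) -> int:
        t = self.codebook.t
        return t * len(self.learners) * t


def _assemble_meta(
    blocks: dict[tuple[str, str], np.ndarray],
    codebook: LabelCodebook,
    learners: list[BaseLearnerSpec],
) -> MetaFeatureMatrix:
    # column order: outer types (codebook order), inner learners (declared
    # order), innermost the t class probabilities in codebook order
    t = codebook.t
    cols = []
    index = {}
    pos = 0
    for c in codebook.types:
        for spec in learners:
            cols.append(blocks[(c, spec.name)])
            index[(c, spec.name)] = (pos, pos + t)
            pos += t
    return MetaFeatureMatrix(values=np.hstack(cols), block_index=index)


def fit(
    data: ExpressionDataset,
    learners: list[BaseLearnerSpec] | None = None,
    k: int = 300,
    folds: int = 3,
    seed: int = 0,
    preprocess: PreprocessSettings | None = None,
    already_normalized: bool = False,
) -> StackingModel:
    """Fit the full two-layer stacking model on a labeled dataset.

    Pipeline: per-cell normalization → one-vs-rest χ² signatures (top-k per
    type) → per-(signature, learner) OOF probability blocks → meta logistic
    regression on the concatenated n×(t·L·t) matrix.  Base learners are then
    refit on their full sub-datasets for test-time transformation.
    """
    if data.labels is None:
        raise ValueError("fit requires a labeled dataset")
    learners = list(learners) if learners is not None else list(DEFAULT_LEARNERS)
    names = [s.name for s in learners]
    if len(set(names)) != len(names):
        raise ValueError("learner names must be unique")
    preprocess = preprocess or PreprocessSettings()

    codebook = LabelCodebook.from_labels(data.labels)
    _check_class_sizes(data.labels, folds)
    norm = data if already_normalized else normalize_cells(data, preprocess)
    signatures = select_signatures(norm, k=k)

    y = codebook.encode(norm.labels)
    blocks: dict[tuple[str, str], np.ndarray] = {}
    base_models: dict[tuple[str, str], object] = {}
    for c in codebook.types:
        sub = build_subdataset(norm, signatures.per_type[c])
        X_full = sub.dense()
        for spec in learners:
            blocks[(c, spec.name)] = oof_transform(
                sub, spec, folds=folds, seed=seed, codebook=codebook
            )
            refit = spec.build(seed=seed)
            refit.fit(X_full, y)
            base_models[(c, spec.name)] = refit

    meta = _assemble_meta(blocks, codebook, learners)
    meta_model = LogisticRegression(C=1.0, max_iter=5000)
    meta_model.fit(meta.values, y)
    logger.info(
        "fitted stacking model: t=%d types, L=%d learners, meta width %d",
        codebook.t, len(learners), meta.width,
    )
    return StackingModel(
        codebook=codebook,
        signatures=signatures,
        base_models=base_models,
        meta_model=meta_model,
        learners=learners,
        preprocess=preprocess,
        folds=folds,
        seed=seed,
    )


def transform_meta(model: StackingModel, aligned: ExpressionDataset) -> MetaFeatureMatrix:
    """First-layer transform of an (already normalized, aligned) dataset."""
    blocks = {}
    for c in model.codebook.types:
        sub = build_subdataset(aligned, model.signatures.per_type[c])
        X = sub.dense()
        for spec in model.learners:
            est = model.base_models[(c, spec.name)]
            blocks[(c, spec.name)] = _full_proba(est, X, model.codebook)
    return _assemble_meta(blocks, model.codebook, model.learners)


def predict_types(
    model: StackingModel,
    test: ExpressionDataset,
    already_normalized: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Predict cell types for a test dataset.

    The test matrix is normalized with the model's own preprocessing
    settings, projected onto the signature gene space (missing genes filled
    with 0, with a warning), pushed through the refit first-layer learners
    into the meta-feature matrix, and classified by the meta-learner.
    Returns the predicted type per cell and the n×t meta-probability matrix.
    A cell whose true type was absent from training is necessarily assigned
    some training type — the model cannot flag novel types.
    """
    norm = test if already_normalized else normalize_cells(test, model.preprocess)
    aligned = align_genes(model.signatures.union_genes(), norm, fill=0.0)
    meta = transform_meta(model, aligned)
    proba = model.meta_model.predict_proba(meta.values)
    # map estimator column order onto codebook order
    full = np.zeros((proba.shape[0], model.codebook.t))
    for col, cls in enumerate(model.meta_model.classes_):
        full[:, int(cls)] = proba[:, col]
    codes = np.argmax(full, axis=1)  # argmax returns first max: codebook-order tie-break
    return model.codebook.decode(codes), full


def save_model(model: StackingModel, path) -> None:
    """Serialize a fitted model (format-versioned joblib archive)."""
    joblib.dump(
        {"format": _MODEL_FORMAT, "version": _MODEL_VERSION, "model": model}, path
    )


def load_model(path) -> StackingModel:
    """Load a model saved by :func:`save_model`.

    Raises :class:`ModelIOError` on corruption or version mismatch.
    """
    try:
        payload = joblib.load(path)
    except Exception as e:  # noqa: BLE001 - any unpickling failure is corruption
        raise ModelIOError(f"corrupt model file: {path} ({e})") from e
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelIOError(f"corrupt model file: {path} (unrecognized payload)")
    if payload.get("version") != _MODEL_VERSION:
        raise ModelIOError(
            f"model version mismatch: file has {payload.get('version')}, "
            f"expected {_MODEL_VERSION}"
        )
    return payload["model"]
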