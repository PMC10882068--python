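"""Serial feature fusion, classifier backends and evaluation reports.

Serial fusion concatenates two feature matrices column-wise: widths d1
and d2 over the same N observations give a fused N x (d1 + d2) matrix.

Classifier backends follow fixed, named configurations:

* ``cubic_svm`` — SVC, polynomial kernel of degree 3, box constraint 1,
  automatic kernel scale, one-vs-one multiclass, standardized inputs.
* ``weighted_knn`` — 10 neighbors, Euclidean distance, squared-inverse
  distance weights, standardized inputs.
* ``narrow_nn`` / ``medium_nn`` / ``wide_nn`` — one hidden ReLU layer of
  10 / 25 / 100 units; ``bilayer_nn`` (10, 10); ``trilayer_nn``
  (10, 10, 10).  All nets: iteration limit 1000, no regularization,
  standardized inputs.

Evaluation derives one-vs-rest TP/TN/FP/FN per class from the confusion
matrix and reports accuracy, sensitivity TP/(TP+FN), false-negative rate
FN/(TP+FN), precision TP/(TP+FP) (all in percent, macro-averaged across
classes) and macro one-vs-rest AUC from class scores.  By construction
sensitivity + FNR = 100 per class.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledFeatureMatrix",
    "ClassifierSpec",
    "EvaluationReport",
    "CLASSIFIER_NAMES",
    "serial_fuse",
    "train_classifier",
    "evaluate_classifier",
]

_NN_LAYERS = {
    "narrow_nn": (10,),
    "medium_nn": (25,),
    "wide_nn": (100,),
    "bilayer_nn": (10, 10),
    "trilayer_nn": (10, 10, 10),
}
CLASSIFIER_NAMES = ("cubic_svm", "weighted_knn", *_NN_LAYERS)


@dataclass
class LabeledFeatureMatrix:
    """N x d feature values with per-row class labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("row count and label count differ")
        if self.feature_names is not None and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"choose from {CLASSIFIER_NAMES}")


def serial_fuse(f1: LabeledFeatureMatrix,
                f2: LabeledFeatureMatrix) -> LabeledFeatureMatrix:
    """Column-wise concatenation; requires equal N and identical labels."""
    if f1.n != f2.n:
        raise ValueError(f"row-count mismatch: {f1.n} vs {f2.n}")
    if not np.array_equal(f1.labels, f2.labels):
        raise ValueError("label vectors differ between the two matrices")
    names = None
    if f1.feature_names is not None and f2.feature_names is not None:
        names = list(f1.feature_names) + list(f2.feature_names)
    return LabeledFeatureMatrix(np.hstack([f1.values, f2.values]),
                                f1.labels.copy(), names)


def _squared_inverse(dists: np.ndarray) -> np.ndarray:
    # zero-distance neighbors (e.g. a training point voting for itself)
    # take all the weight, matching the limit of 1/d^2
    with np.errstate(divide="ignore"):
        w = 1.0 / dists ** 2
    inf_rows = np.isinf(w).any(axis=1)
    if inf_rows.any():
        w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


def _build_estimator(spec: ClassifierSpec, seed: int):
    if spec.name == "cubic_svm":
        est = SVC(kernel="poly", degree=3, C=1.0, gamma="scale",
                  decision_function_shape="ovr", random_state=seed)
    elif spec.name == "weighted_knn":
        est = KNeighborsClassifier(n_neighbors=10, metric="euclidean",
                                   weights=_squared_inverse)
    else:
        est = MLPClassifier(hidden_layer_sizes=_NN_LAYERS[spec.name],
                            activation="relu", alpha=0.0, max_iter=1000,
                            random_state=seed)
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", est))
    return Pipeline(steps)


class FittedClassifier:
    """A fitted backend plus bookkeeping for scoring."""

    def __init__(self, pipeline: Pipeline, spec: ClassifierSpec,
                 classes: np.ndarray):
        self.pipeline = pipeline
        self.spec = spec
        self.classes = classes

    def predict(self, X) -> np.ndarray:
        return self.pipeline.predict(np.atleast_2d(X))

    def scores(self, X) -> np.ndarray:
        """Per-class scores for ranking (probabilities or decision values)."""
        X = np.atleast_2d(X)
        clf = self.pipeline.named_steps["clf"]
        if hasattr(clf, "predict_proba"):
            return self.pipeline.predict_proba(X)
        return self.pipeline.decision_function(X)


def train_classifier(train: LabeledFeatureMatrix, spec: ClassifierSpec,
                     seed: int = 0) -> FittedClassifier:
    """Fit a backend on the training matrix (scaler fitted on train only)."""
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training set has a single class")
    pipe = _build_estimator(spec, seed)
    pipe.fit(train.values, train.labels)
    return FittedClassifier(pipe, spec, classes)


@dataclass
class EvaluationReport:
    classes: np.ndarray
    confusion_matrix: np.ndarray
    accuracy: float                       # percent, overall
    sensitivity: dict = field(default_factory=dict)       # percent per class
    false_negative_rate: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    macro_sensitivity: float = np.nan
    macro_false_negative_rate: float = np.nan
    macro_precision: float = np.nan
    macro_auc: float = np.nan
    elapsed_seconds: float = 0.0
    unseen_labels: list = field(default_factory=list)


def evaluate_classifier(model: FittedClassifier,
                        test: LabeledFeatureMatrix) -> EvaluationReport:
    """Confusion-matrix-based report with macro-averaged percent metrics."""
    if test.n == 0:
        raise ValueError("empty test set")
    t0 = time.perf_counter()
    pred = model.predict(test.values)
    classes = np.unique(np.concatenate([model.classes, np.unique(test.labels)]))
    unseen = sorted(set(np.unique(test.labels)) - set(model.classes))
    cm = _sk_confusion(test.labels, pred, labels=classes)

    report = EvaluationReport(classes=classes, confusion_matrix=cm,
                              accuracy=100.0 * np.trace(cm) / cm.sum(),
                              unseen_labels=list(unseen))
    sens, fnrs, precs = [], [], []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        s = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        p = 100.0 * tp / (tp + fp) if tp + fp else np.nan
        report.sensitivity[c] = s
        report.false_negative_rate[c] = 100.0 - s if np.isfinite(s) else np.nan
        report.precision[c] = p
        if np.isfinite(s):
            sens.append(s)
            fnrs.append(100.0 - s)
        if np.isfinite(p):
            precs.append(p)
    report.macro_sensitivity = float(np.mean(sens)) if sens else np.nan
    report.macro_false_negative_rate = float(np.mean(fnrs)) if fnrs else np.nan
    report.macro_precision = float(np.mean(precs)) if precs else np.nan

    try:
        scores = model.scores(test.values)
        if len(model.classes) == 2:
            col = scores[:, 1] if scores.ndim == 2 else scores
            auc = roc_auc_score((test.labels == model.classes[1]).astype(int), col)
            report.auc = {model.classes[0]: auc, model.classes[1]: auc}
            report.macro_auc = float(auc)
        else:
            aucs = {}
            for i, c in enumerate(model.classes):
                y_bin = (test.labels == c).astype(int)
                if 0 < y_bin.sum() < len(y_bin):
                    aucs[c] = roc_auc_score(y_bin, scores[:, i])
            report.auc = aucs
            report.macro_auc = float(np.mean(list(aucs.values()))) if aucs else np.nan
    except Exception:  # scores unavailable for some backend/test combination
        report.macro_auc = np.nan
    report.elapsed_seconds = time.perf_counter() - t0
    return report
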