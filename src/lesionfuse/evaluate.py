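"""Multi-classifier evaluation under stratified 10-fold cross-validation.

The classifier roster mirrors the named presets common in point-and-
click classification tools: narrow/medium/wide neural networks (one
hidden layer of 10/25/100 units), bilayered and trilayered networks
(2 or 3 layers of 10), quadratic and cubic SVMs (polynomial kernels of
degree 2 and 3), a coarse Gaussian SVM (RBF with a large kernel scale),
fine KNN (k = 1), a bagged-tree ensemble, and a fine decision tree.
Neural networks and SVMs are fit on standardized features; KNN and the
trees consume the raw columns.

Metrics are computed from the fold-aggregated confusion matrix:
accuracy, macro recall, macro precision and macro F1 (all in percent),
and the false-negative rate FNR = 100 - macro recall.  Macro averaging
gives each class equal weight regardless of size, which is what makes
the FNR/recall identity hold exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "ClassifierSpec",
    "MetricsRow",
    "EvalReport",
    "DEFAULT_ROSTER",
    "make_classifier",
    "kfold_cv",
    "compute_metrics",
    "benchmark",
]


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparams: tuple = ()

    def resolved(self) -> dict:
        return dict(self.hyperparams)


DEFAULT_ROSTER: list[ClassifierSpec] = [
    ClassifierSpec("narrow_nn"),
    ClassifierSpec("medium_nn"),
    ClassifierSpec("wide_nn"),
    ClassifierSpec("bilayered_nn"),
    ClassifierSpec("quadratic_svm"),
    ClassifierSpec("cubic_svm"),
    ClassifierSpec("coarse_gaussian_svm"),
    ClassifierSpec("fine_knn"),
    ClassifierSpec("ensemble_bagged_tree"),
    ClassifierSpec("fine_tree"),
]


def _scaled(est):
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def make_classifier(spec: ClassifierSpec, n_features: int, seed: int):
    """Instantiate the estimator a roster name stands for."""
    hp = spec.resolved()
    name = spec.name
    if name == "narrow_nn":
        return _scaled(MLPClassifier((10,), max_iter=1000, random_state=seed, **hp))
    if name == "medium_nn":
        return _scaled(MLPClassifier((25,), max_iter=1000, random_state=seed, **hp))
    if name == "wide_nn":
        return _scaled(MLPClassifier((100,), max_iter=1000, random_state=seed, **hp))
    if name == "bilayered_nn":
        return _scaled(MLPClassifier((10, 10), max_iter=1000, random_state=seed, **hp))
    if name == "trilayered_nn":
        return _scaled(
            MLPClassifier((10, 10, 10), max_iter=1000, random_state=seed, **hp)
        )
    if name == "quadratic_svm":
        return _scaled(SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", **hp))
    if name == "cubic_svm":
        return _scaled(SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", **hp))
    if name == "coarse_gaussian_svm":
        # coarse preset: kernel scale 4 * sqrt(D)  =>  gamma = 1 / (16 D)
        gamma = hp.pop("gamma", 1.0 / (16.0 * max(n_features, 1)))
        return _scaled(SVC(kernel="rbf", gamma=gamma, **hp))
    if name == "fine_knn":
        return KNeighborsClassifier(n_neighbors=1, **hp)
    if name == "ensemble_bagged_tree":
        return BaggingClassifier(
            DecisionTreeClassifier(random_state=seed),
            n_estimators=hp.pop("n_estimators", 30),
            random_state=seed,
            **hp,
        )
    if name == "fine_tree":
        return DecisionTreeClassifier(
            max_leaf_nodes=hp.pop("max_leaf_nodes", 100), random_state=seed, **hp
        )
    raise ConfigurationError(f"unknown classifier {name!r}")


def kfold_cv(
    features, labels, clf_spec: ClassifierSpec, k: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified k-fold: each sample predicted once by a model that never
    saw it; returns (out-of-fold predictions, aggregate confusion matrix)."""
    values = np.asarray(
        features.values if hasattr(features, "values") else features, float
    )
    labels = np.asarray(labels, int)
    classes = np.unique(labels)
    counts = np.bincount(labels, minlength=classes.max() + 1)
    if counts[classes].min() < k:
        raise InvalidArgumentError(
            f"every class needs >= {k} samples for {k}-fold CV"
        )
    est = make_classifier(clf_spec, values.shape[1], seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty(len(labels), dtype=int)
    for train_idx, test_idx in skf.split(values, labels):
        model = clone(est)
        model.fit(values[train_idx], labels[train_idx])
        preds[test_idx] = model.predict(values[test_idx])
    confusion = confusion_matrix(labels, preds, labels=classes)
    return preds, confusion


@dataclass
class MetricsRow:
    """One table row, metric values in percent."""

    classifier: str
    accuracy: float
    recall: float
    precision: float
    f1: float
    fnr: float
    train_time_s: float = 0.0


def compute_metrics(confusion: np.ndarray, classifier: str = "") -> MetricsRow:
    """Accuracy and macro recall/precision/F1 (percent) from a confusion
    matrix; FNR is the complement of macro recall.

    A class whose predicted column is empty has undefined precision and
    contributes 0 to the macro precision average.
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total < 1:
        raise InvalidArgumentError("confusion matrix is empty")
    diag = np.diag(confusion)
    row_sums = confusion.sum(axis=1)
    col_sums = confusion.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rec = np.where(row_sums > 0, diag / row_sums, 0.0)
        prec = np.where(col_sums > 0, diag / col_sums, 0.0)
        f1 = np.where(rec + prec > 0, 2 * rec * prec / (rec + prec), 0.0)
    # classes absent from the data (empty rows) are excluded from macro
    present = row_sums > 0
    accuracy = 100.0 * diag.sum() / total
    recall = 100.0 * rec[present].mean()
    precision = 100.0 * prec[present].mean()
    f1_macro = 100.0 * f1[present].mean()
    return MetricsRow(
        classifier=classifier,
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        f1=f1_macro,
        fnr=100.0 - recall,
    )


@dataclass
class EvalReport:
    rows: list[MetricsRow]
    confusions: dict[str, np.ndarray]
    folds: int

    def to_tsv(self) -> str:
        header = "Classifiers\tAccuracy(%)\tRecall(%)\tPrecision(%)\tF1 Score\tFNR\tTime (sec)"
        lines = [header]
        for r in self.rows:
            lines.append(
                f"{r.classifier}\t{r.accuracy:.2f}\t{r.recall:.2f}\t"
                f"{r.precision:.2f}\t{r.f1:.2f}\t{r.fnr:.2f}\t{r.train_time_s:.2f}"
            )
        return "\n".join(lines) + "\n"


def benchmark(
    features,
    labels,
    roster: list[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Cross-validate every roster classifier on the same folds.

    Rows keep roster order; wall-clock time per classifier is recorded
    for information only (it is hardware-dependent and never asserted).
    """
    roster = roster if roster is not None else DEFAULT_ROSTER
    if not roster:
        raise InvalidArgumentError("classifier roster is empty")
    labels = np.asarray(labels, int)
    rows, confusions = [], {}
    for spec in roster:
        t0 = time.perf_counter()
        _, confusion = kfold_cv(features, labels, spec, k=k, seed=seed)
        elapsed = time.perf_counter() - t0
        row = compute_metrics(confusion, classifier=spec.name)
        row.train_time_s = elapsed
        rows.append(row)
        confusions[spec.name] = confusion
    return EvalReport(rows=rows, confusions=confusions, folds=k)
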