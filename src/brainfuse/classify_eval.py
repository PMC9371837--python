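"""Multi-classifier cross-validated evaluation with a full metric suite.

Nine classifier presets (translations of the common MATLAB Classification
Learner presets to scikit-learn estimators) are trained under stratified
k-fold cross-validation; out-of-fold predictions are pooled into a single
confusion matrix per classifier, from which macro one-vs-rest sensitivity,
FNR, precision, FPR and AUC are computed.  Prediction time (total wall time
of the predict calls) is reported for parity but is hardware-dependent and
never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataio import FeatureMatrix
from .fuse_reduce import pca_fit, pca_transform

CLASSIFIER_NAMES = (
    "fine_tree", "linear_discriminant", "cubic_svm", "boosted_trees",
    "bagged_trees", "subspace_discriminant", "narrow_nn", "medium_nn",
    "wide_nn",
)


@dataclass
class ClassifierSpec:
    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; choose from "
                             f"{CLASSIFIER_NAMES}")

    def build(self):
        return _build_estimator(self.name, self.hyperparams, self.seed)


def _build_estimator(name: str, hp: dict, seed: int):
    hp = dict(hp)
    if name == "fine_tree":
        # "fine tree" preset: up to 100 splits
        return DecisionTreeClassifier(max_leaf_nodes=hp.pop("max_leaf_nodes", 101),
                                      random_state=seed, **hp)
    if name == "linear_discriminant":
        return LinearDiscriminantAnalysis(**hp)
    if name == "cubic_svm":
        return SVC(kernel="poly", degree=hp.pop("degree", 3),
                   gamma=hp.pop("gamma", "scale"), coef0=hp.pop("coef0", 1.0),
                   C=hp.pop("C", 1.0), random_state=seed, **hp)
    if name == "boosted_trees":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp.pop("max_depth", 2)),
            n_estimators=hp.pop("n_estimators", 30), random_state=seed, **hp)
    if name == "bagged_trees":
        return RandomForestClassifier(n_estimators=hp.pop("n_estimators", 30),
                                      random_state=seed, **hp)
    if name == "subspace_discriminant":
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=hp.pop("n_estimators", 30),
            max_features=hp.pop("max_features", 0.5),
            bootstrap=False, random_state=seed, **hp)
    if name in ("narrow_nn", "medium_nn", "wide_nn"):
        width = {"narrow_nn": 10, "medium_nn": 25, "wide_nn": 100}[name]
        return MLPClassifier(hidden_layer_sizes=(hp.pop("hidden", width),),
                             max_iter=hp.pop("max_iter", 400),
                             random_state=seed, **hp)
    raise ValueError(name)


@dataclass
class ConfusionMatrix:
    """C×C counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C×C for C classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0


def compute_metrics(cm: ConfusionMatrix,
                    scores: np.ndarray | None = None,
                    y_true: np.ndarray | None = None) -> dict:
    """Macro one-vs-rest metric suite from a pooled confusion matrix.

    Percentages for accuracy, sensitivity, FNR and precision; FPR and AUC as
    fractions (the usual reporting convention).  Per class, one-vs-rest:
    sensitivity = TP/(TP+FN), precision = TP/(TP+FP), FPR = FP/(FP+TN),
    FNR = 100 − sensitivity; reported values are unweighted macro averages so
    the identity sensitivity + FNR = 100 holds exactly.  A class with a zero
    denominator contributes 0 to the average and is listed under
    ``degenerate_classes``.  AUC (macro one-vs-rest) requires per-sample
    ``scores`` (N×C) aligned with ``y_true``.
    """
    counts = cm.counts.astype(float)
    c = counts.shape[0]
    total = counts.sum()
    sens, prec, fpr = [], [], []
    degenerate = []
    for i in range(c):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0 or tp + fp == 0 or fp + tn == 0:
            degenerate.append(cm.class_order[i])
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        prec.append(tp / (tp + fp) if tp + fp else 0.0)
        fpr.append(fp / (fp + tn) if fp + tn else 0.0)

    sensitivity = 100.0 * float(np.mean(sens))
    metrics = {
        "accuracy": 100.0 * float(np.trace(counts) / total) if total else 0.0,
        "sensitivity": sensitivity,
        "fnr": 100.0 - sensitivity,
        "precision": 100.0 * float(np.mean(prec)),
        "fpr": float(np.mean(fpr)),
        "degenerate_classes": degenerate,
    }
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true aligned with scores")
        y_true = np.asarray(y_true)
        aucs = [
            roc_auc_score((y_true == cls).astype(int), scores[:, i])
            for i, cls in enumerate(cm.class_order)
        ]
        metrics["auc"] = float(np.mean(aucs))
    return metrics


def _predict_scores(estimator, X: np.ndarray, classes) -> np.ndarray:
    """Per-class score matrix in the order ``classes``."""
    if hasattr(estimator, "predict_proba"):
        raw = estimator.predict_proba(X)
    else:
        raw = estimator.decision_function(X)
        if raw.ndim == 1:
            raw = np.column_stack([-raw, raw])
    order = [list(estimator.classes_).index(c) for c in classes]
    return raw[:, order]


@dataclass
class ClassifierReport:
    name: str
    confusion: ConfusionMatrix
    metrics: dict
    prediction_time: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "confusion": self.confusion.counts.tolist(),
            "class_order": list(self.confusion.class_order),
            "metrics": dict(self.metrics),
            "prediction_time": self.prediction_time,
        }


@dataclass
class EvalReport:
    classifiers: dict[str, ClassifierReport]
    folds: int
    seed: int
    n_samples: int
    n_features: int
    fold_assignment: list[int]

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "fold_assignment": list(self.fold_assignment),
            "classifiers": {k: v.to_dict() for k, v in self.classifiers.items()},
        }

    def best(self, metric: str = "accuracy") -> tuple[str, float]:
        name = max(self.classifiers, key=lambda k: self.classifiers[k].metrics[metric])
        return name, self.classifiers[name].metrics[metric]


def default_specs(names=CLASSIFIER_NAMES, seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(name=n, seed=seed) for n in names]


def crossval_evaluate(fm: FeatureMatrix,
                      specs: list[ClassifierSpec] | None = None,
                      folds: int = 10,
                      seed: int = 0,
                      pca_k: int | None = None,
                      standardize: bool = True) -> EvalReport:
    """Stratified k-fold evaluation of the classifier bank.

    Out-of-fold predictions are pooled into one confusion matrix per
    classifier.  When ``pca_k`` is given, PCA is fit on each training fold
    only and applied to the held-out fold, so no test information leaks into
    the projection; the same train-only rule applies to standardization.
    """
    if specs is None:
        specs = default_specs(seed=seed)
    classes = fm.classes
    counts = {c: int((fm.y == c).sum()) for c in classes}
    for c, k in counts.items():
        if k < folds:
            raise ValueError(f"class {c!r} has {k} samples; "
                             f"needs >= {folds} for {folds}-fold CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(fm.X, fm.y))
    fold_assignment = np.empty(fm.n, dtype=int)
    for f, (_, te) in enumerate(splits):
        fold_assignment[te] = f

    estimators = {s.name: s.build() for s in specs}
    y_pred = {n: np.empty(fm.n, dtype=object) for n in estimators}
    y_score = {n: np.empty((fm.n, len(classes))) for n in estimators}
    pred_time = {n: 0.0 for n in estimators}

    for tr, te in splits:
        X_tr, X_te = fm.X[tr], fm.X[te]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        if pca_k is not None:
            k = min(pca_k, len(tr) - 1, X_tr.shape[1])
            model = pca_fit(X_tr, k)
            X_tr = pca_transform(model, X_tr)
            X_te = pca_transform(model, X_te)
        for name, est in estimators.items():
            fitted = clone(est).fit(X_tr, fm.y[tr])
            t0 = time.perf_counter()
            y_pred[name][te] = fitted.predict(X_te)
            pred_time[name] += time.perf_counter() - t0
            y_score[name][te] = _predict_scores(fitted, X_te, classes)

    reports = {}
    for name in estimators:
        cm = ConfusionMatrix(
            counts=_sk_confusion(fm.y, y_pred[name], labels=classes),
            class_order=classes)
        metrics = compute_metrics(cm, scores=y_score[name], y_true=fm.y)
        reports[name] = ClassifierReport(name=name, confusion=cm,
                                         metrics=metrics,
                                         prediction_time=pred_time[name])
    return EvalReport(classifiers=reports, folds=folds, seed=seed,
                      n_samples=fm.n, n_features=fm.d,
                      fold_assignment=fold_assignment.tolist())
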