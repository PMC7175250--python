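"""Semi-supervised polymorph classification.

Training labels are produced by simple single-feature threshold rules scoped
to individual images (within one image, COM / COD / debris separate cleanly
on e.g. area or maximum intensity, even though no single threshold works
across images).  A support vector machine with a cubic (degree-3
polynomial) kernel is trained on standardized features and evaluated by
stratified fivefold cross-validation; per-class precision, recall and F1
are reported alongside the pooled confusion matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .imaging_io import CLASS_CODES

_MODEL_FORMAT_VERSION = 1


class AnnotationConflictError(ValueError):
    """Two equal-precedence rules assign different classes to one crystal."""


class StratificationError(ValueError):
    """A class has too few examples for the requested fold count."""


@dataclass(frozen=True)
class AnnotationRule:
    """Single-feature threshold rule assigning a class within an image scope.

    ``comparator`` is one of ``<  <=  >  >=  between`` (between uses
    ``threshold_lo < x < threshold_hi``).  ``scope`` is an image id or
    ``"*"`` for all images.  ``precedence`` defaults to the rule's position
    in the rule list, so later rules override earlier ones; rules given the
    same explicit precedence must not conflict.
    """

    feature: str
    comparator: str
    threshold_lo: float
    assigned_class: int
    threshold_hi: float | None = None
    scope: str = "*"
    precedence: int | None = None

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.comparator not in ("<", "<=", ">", ">=", "between"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.assigned_class not in CLASS_CODES:
            raise ValueError(f"class must be one of {CLASS_CODES}")
        if self.comparator == "between":
            if self.threshold_hi is None or not self.threshold_lo < self.threshold_hi:
                raise ValueError("between-rule requires threshold_lo < threshold_hi")

    def matches(self, values: pd.Series) -> pd.Series:
        x = values.astype(float)
        if self.comparator == "<":
            return x < self.threshold_lo
        if self.comparator == "<=":
            return x <= self.threshold_lo
        if self.comparator == ">":
            return x > self.threshold_lo
        if self.comparator == ">=":
            return x >= self.threshold_lo
        return (x > self.threshold_lo) & (x < self.threshold_hi)


def annotate(crystals: pd.DataFrame, rules: list[AnnotationRule],
             image_column: str = "image_id") -> pd.DataFrame:
    """Apply threshold rules to a feature table, returning the labeled subset.

    A crystal receives a label iff, among the rules matching it (respecting
    image scope), a unique highest-precedence rule exists; crystals matched
    by no rule are excluded from the training table.  Equal-precedence
    conflicts raise :class:`AnnotationConflictError` listing the crystals.
    """
    if not rules:
        return crystals.iloc[0:0].assign(label=pd.Series(dtype=int))
    for rule in rules:
        if rule.feature not in crystals.columns:
            raise ValueError(f"feature {rule.feature!r} missing from table")
    prec = [r.precedence if r.precedence is not None else i for i, r in enumerate(rules)]
    n = len(crystals)
    matches = []
    for rule in rules:
        sel = rule.matches(crystals[rule.feature]).to_numpy()
        if rule.scope != "*" and image_column in crystals.columns:
            sel &= (crystals[image_column].astype(str) == str(rule.scope)).to_numpy()
        matches.append(sel)
    best_prec = np.full(n, -np.inf)
    for sel, p in zip(matches, prec):
        best_prec = np.where(sel, np.maximum(best_prec, p), best_prec)
    assigned = np.full(n, -1)
    conflict = np.zeros(n, dtype=bool)
    for rule, sel, p in zip(rules, matches, prec):
        top = sel & (best_prec == p)
        conflict |= top & (assigned >= 0) & (assigned != rule.assigned_class)
        assigned = np.where(top & (assigned < 0), rule.assigned_class, assigned)
    if conflict.any():
        idx = np.nonzero(conflict)[0]
        if "segment_id" in crystals.columns:
            ids = crystals.iloc[idx]["segment_id"].tolist()
        else:
            ids = idx.tolist()
        raise AnnotationConflictError(
            f"conflicting equal-precedence rules for crystal id(s) {ids}"
        )
    labeled = crystals[assigned >= 0].copy()
    labeled["label"] = assigned[assigned >= 0].astype(int)
    return labeled


@dataclass
class ClassifierModel:
    """Trained cubic-SVM with its standardization and feature schema."""

    pipeline: Pipeline
    feature_names: list[str]
    classes: list[int]
    fingerprint: str = ""
    format_version: int = _MODEL_FORMAT_VERSION

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, ClassifierModel):
            raise TypeError("artifact is not a ClassifierModel")
        return model


@dataclass
class CVReport:
    """Stratified cross-validation summary (pooled over folds)."""

    n_folds: int
    overall_accuracy: float
    confusion_matrix: np.ndarray        # rows = true, cols = predicted
    classes: list[int]
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    n_per_class: dict[int, int]
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "overall_accuracy": self.overall_accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "classes": self.classes,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "n_per_class": {str(k): v for k, v in self.n_per_class.items()},
            "seed": self.seed,
        }


def make_svm(C: float = 1.0, degree: int = 3, coef0: float = 1.0,
             gamma: str | float = "scale") -> Pipeline:
    """Standardizer + polynomial-kernel SVM ('cubic SVM' at degree 3)."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="poly", degree=degree, C=C, coef0=coef0, gamma=gamma)),
    ])


def _content_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row order keyed on a content hash, so CV ignores input row order."""
    digests = [
        hashlib.sha256(np.ascontiguousarray(np.round(row, 9)).tobytes() + bytes([lab]))
        .hexdigest()
        for row, lab in zip(X, y)
    ]
    return np.argsort(digests, kind="stable")


def train(training: pd.DataFrame, seed: int = 0, n_folds: int = 5,
          C: float = 1.0, degree: int = 3, coef0: float = 1.0,
          gamma: str | float = "scale") -> tuple[ClassifierModel, CVReport]:
    """Train the cubic SVM and report stratified fivefold CV performance.

    Standardization is fit within each training fold (no test-fold leakage);
    the final model is refit on all rows.  Requires >= 2 classes and at
    least ``n_folds`` examples per class.
    """
    missing = [f for f in FEATURE_NAMES if f not in training.columns]
    if missing:
        raise ValueError(f"training table missing feature(s): {missing}")
    if "label" not in training.columns:
        raise ValueError("training table has no 'label' column")
    X = training[FEATURE_NAMES].to_numpy(dtype=float)
    y = training["label"].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    for cls, cnt in zip(classes, counts):
        if cnt < n_folds:
            raise StratificationError(
                f"class {cls} has only {cnt} example(s); needs >= {n_folds} "
                f"for {n_folds}-fold stratified CV"
            )
    order = _content_order(X, y)
    Xo, yo = X[order], y[order]
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pipe = make_svm(C=C, degree=degree, coef0=coef0, gamma=gamma)
    y_pred = cross_val_predict(pipe, Xo, yo, cv=cv)
    report = evaluate(yo, y_pred, classes=list(classes))
    report.n_folds = n_folds
    report.seed = seed
    pipe.fit(Xo, yo)
    fingerprint = hashlib.sha256(
        Xo.tobytes() + yo.tobytes() + str(seed).encode()
    ).hexdigest()[:16]
    model = ClassifierModel(
        pipeline=pipe,
        feature_names=list(FEATURE_NAMES),
        classes=[int(c) for c in classes],
        fingerprint=fingerprint,
    )
    return model, report


def classify(model: ClassifierModel, crystals: pd.DataFrame) -> np.ndarray:
    """Hard class labels for a feature table under a trained model."""
    missing = [f for f in model.feature_names if f not in crystals.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    if len(crystals) == 0:
        return np.array([], dtype=int)
    X = crystals[model.feature_names].to_numpy(dtype=float)
    return model.pipeline.predict(X).astype(int)


def evaluate(y_true, y_pred, classes: list[int] | None = None) -> CVReport:
    """Confusion matrix (rows = true) and per-class precision / recall / F1.

    F1 is the harmonic mean of precision and recall, defined as 0 when
    precision + recall = 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    observed = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not observed <= set(CLASS_CODES):
        raise ValueError(f"labels outside the class vocabulary: {sorted(observed - set(CLASS_CODES))}")
    if classes is None:
        classes = sorted(observed)
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total if total else 0.0
    precision, recall, f1, n_per_class = {}, {}, {}, {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        p = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
        r = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
        precision[int(cls)] = float(p)
        recall[int(cls)] = float(r)
        f1[int(cls)] = float(2 * p * r / (p + r)) if (p + r) else 0.0
        n_per_class[int(cls)] = int(cm[i, :].sum())
    return CVReport(
        n_folds=0,
        overall_accuracy=accuracy,
        confusion_matrix=cm,
        classes=[int(c) for c in classes],
        precision=precision,
        recall=recall,
        f1=f1,
        n_per_class=n_per_class,
    )
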