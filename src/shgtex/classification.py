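"""Linear-SVM classification under stratified 9-fold cross-validation.

Each of the four pairwise models (within-group first-vs-second diagnosis,
and across-group first/second diagnoses) is evaluated per channel: features
are z-scored with training-fold statistics only, a soft-margin linear SVM
is fitted, and every fold reports accuracy, the ROC curve with trapezoidal
AUC, and a 2x2 confusion matrix. The fold with the best accuracy is
highlighted and its confusion matrix reported, alongside the across-fold
average accuracy.

The cross-validation unit is the per-angle datapoint by default (each
angle of each image is an independent record); an optional grouped mode
keeps all angles of one image — or all images of one patient — on the same
side of every split, for leakage-sensitive analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .feature_table import COMPARISONS, select_class
from .texture import FEATURE_NAMES


class ConfigurationError(ValueError):
    """Raised for invalid cross-validation setups (k, class sizes)."""


class UndefinedAUCError(ValueError):
    """Raised when a ROC curve is requested with only one class present."""


@dataclass
class FoldResult:
    """Evaluation of one cross-validation fold."""

    fold_index: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    accuracy: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    auc: float
    confusion: np.ndarray  # 2x2, rows = true class, cols = predicted


@dataclass
class ComparisonReport:
    """All folds of one pairwise model on one channel."""

    model_name: str
    channel: str
    class_a: tuple[str, str]
    class_b: tuple[str, str]
    folds: list[FoldResult]
    best_fold_index: int
    best_fold_accuracy: float
    average_accuracy: float
    mean_auc: float
    n_datapoints: int
    seed: int
    c_param: float
    grouping: str = "datapoint"
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "channel": self.channel,
            "class_a": list(self.class_a),
            "class_b": list(self.class_b),
            "best_fold_index": self.best_fold_index,
            "best_fold_accuracy": self.best_fold_accuracy,
            "average_accuracy": self.average_accuracy,
            "mean_auc": self.mean_auc,
            "n_datapoints": self.n_datapoints,
            "seed": self.seed,
            "c_param": self.c_param,
            "grouping": self.grouping,
            "feature_names": list(self.feature_names),
            "folds": [
                {
                    "fold_index": f.fold_index,
                    "train_indices": f.train_indices.tolist(),
                    "test_indices": f.test_indices.tolist(),
                    "accuracy": f.accuracy,
                    "auc": f.auc,
                    "roc_points": f.roc_points.tolist(),
                    "confusion": f.confusion.tolist(),
                }
                for f in self.folds
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


class TextureSVM(BaseEstimator, ClassifierMixin):
    """Soft-margin linear SVM on z-scored texture features.

    A thin sklearn estimator bundling per-feature standardization (fitted
    on the training data only) with ``SVC(kernel="linear")``. The linear
    kernel keeps the decision function interpretable as a weighted sum of
    the texture features.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray
        The two class labels.
    coef_ : ndarray, shape (1, n_features)
        Weights in standardized feature space.
    intercept_ : float
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self.pipeline_ = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="linear", C=self.C)),
            ]
        ).fit(X, y)
        self.classes_ = self.pipeline_["svm"].classes_
        self.coef_ = self.pipeline_["svm"].coef_
        self.intercept_ = self.pipeline_["svm"].intercept_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(X)


def fit_linear_svm(
    train_features: np.ndarray, train_labels: np.ndarray, c_param: float = 1.0
) -> TextureSVM:
    """Fit a linear SVM (standardization included); thin estimator wrapper."""
    return TextureSVM(C=c_param).fit(train_features, train_labels)


def stratified_kfold(
    labels, k: int = 9, seed: int = 0, groups=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold split of a binary label list.

    Every fold's per-class test count is within one of ``n_class / k``; the
    test sets partition the index range. With ``groups`` given, records
    sharing a group id never straddle a train/test boundary (per-class
    counts are then only approximately balanced).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ConfigurationError(f"k must be >= 2 for held-out evaluation, got {k}")
    values, counts = np.unique(labels, return_counts=True)
    for value, count in zip(values, counts):
        if count < k:
            raise ConfigurationError(
                f"class {value!r} has only {count} record(s); needs >= k = {k}"
            )
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [
            (train, test) for train, test in splitter.split(np.zeros(len(labels)), labels)
        ]
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, test)
        for train, test in splitter.split(np.zeros(len(labels)), labels, groups)
    ]


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC from decision scores.

    Thresholds sweep the unique score values; tied scores are grouped so
    ties appear as diagonal ROC segments. Returns the (FPR, TPR) polyline
    from (0, 0) to (1, 1) and its trapezoidal area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("ROC/AUC undefined with a single class present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


def run_comparison(
    records: pd.DataFrame,
    comparison: str,
    channel: str = "SHG",
    k: int = 9,
    seed: int = 0,
    c_param: float = 1.0,
    grouping: str = "datapoint",
) -> ComparisonReport:
    """Cross-validate one pairwise model on one channel's cleaned records.

    ``grouping`` is ``"datapoint"`` (default; every per-angle record is an
    independent CV unit, matching the study's datapoint counts),
    ``"image"`` (all angles of one field stay together) or ``"patient"``.

    The positive class for ROC purposes is ``class_b`` (the comparison's
    second selector). Best fold = highest accuracy, ties broken toward the
    lower fold index.
    """
    if comparison not in COMPARISONS:
        raise ValueError(
            f"unknown comparison {comparison!r}; choose from {sorted(COMPARISONS)}"
        )
    if grouping not in ("datapoint", "image", "patient"):
        raise ValueError(f"unknown grouping {grouping!r}")
    sel_a, sel_b = COMPARISONS[comparison]
    sub = records[records["channel"] == channel]
    part_a = select_class(sub, sel_a)
    part_b = select_class(sub, sel_b)
    data = pd.concat([part_a, part_b], ignore_index=True)
    if data.empty:
        raise ConfigurationError(f"no records for comparison {comparison!r}/{channel}")
    X = data[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.where(
        (data["group"] == sel_b[0]) & (data["diagnosis"] == sel_b[1]), 1, 0
    )
    groups = None
    if grouping == "image":
        groups = data["field_id"].to_numpy()
    elif grouping == "patient":
        groups = data["patient_id"].to_numpy()

    folds: list[FoldResult] = []
    for fold_index, (train, test) in enumerate(stratified_kfold(y, k, seed, groups)):
        model = TextureSVM(C=c_param).fit(X[train], y[train])
        pred = model.predict(X[test])
        scores = model.decision_function(X[test])
        acc = float((pred == y[test]).mean())
        cm = confusion_matrix(y[test], pred, labels=[0, 1])
        try:
            points, auc = roc_auc(scores, y[test])
        except UndefinedAUCError:
            points, auc = np.array([[0.0, 0.0], [1.0, 1.0]]), float("nan")
        folds.append(FoldResult(fold_index, train, test, acc, points, auc, cm))

    accuracies = np.array([f.accuracy for f in folds])
    best = int(np.argmax(accuracies))  # argmax takes the lowest index on ties
    return ComparisonReport(
        model_name=comparison,
        channel=channel,
        class_a=sel_a,
        class_b=sel_b,
        folds=folds,
        best_fold_index=best,
        best_fold_accuracy=float(accuracies[best]),
        average_accuracy=float(accuracies.mean()),
        mean_auc=float(np.nanmean([f.auc for f in folds])),
        n_datapoints=int(len(data)),
        seed=seed,
        c_param=c_param,
        grouping=grouping,
    )


def plot_roc_folds(report: ComparisonReport, path: str | Path) -> None:
    """Overlay every fold's ROC curve, highlighting the best fold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for f in report.folds:
        best = f.fold_index == report.best_fold_index
        ax.plot(
            f.roc_points[:, 0],
            f.roc_points[:, 1],
            lw=2.5 if best else 1.0,
            alpha=1.0 if best else 0.5,
            label=f"fold {f.fold_index} (AUC {f.auc:.2f})" + (" *best*" if best else ""),
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{report.model_name} ({report.channel})")
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_best_confusion(report: ComparisonReport, path: str | Path) -> None:
    """Heatmap of the best-performing fold's confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.folds[report.best_fold_index].confusion
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm, cmap="Blues")
    names = ["/".join(report.class_a), "/".join(report.class_b)]
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
    ax.set_xticks([0, 1], names, rotation=20, fontsize=7)
    ax.set_yticks([0, 1], names, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(
        f"{report.model_name} ({report.channel}), fold {report.best_fold_index}",
        fontsize=9,
    )
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
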