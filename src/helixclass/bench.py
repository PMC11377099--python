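"""Benchmark of 15 classification algorithms on the feature matrix.

Protocol: per random seed, a stratified 80/20 train/test split; 10-fold
cross-validated accuracy on the training portion; held-out test metrics
(accuracy, weighted precision/recall/f1, macro one-vs-rest ROC AUC) and
the train-test gap (train accuracy minus test accuracy) as an
overfitting indicator.  All estimators run at library defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import (accuracy_score, auc,
                             precision_recall_fscore_support, roc_curve)
from sklearn.model_selection import (StratifiedKFold, cross_val_score,
                                     train_test_split)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "CLASSIFIER_NAMES",
    "MetricSet",
    "BenchResult",
    "make_classifier",
    "compute_metrics",
    "roc_auc_multiclass",
    "compare_classifiers",
]

CLASSIFIER_NAMES = (
    "Nearest Neighbours",
    "Linear SVM",
    "Polynomial SVM",
    "RBF SVM",
    "Gaussian Process",
    "Gradient Boosting",
    "Decision Tree",
    "Extra Trees",
    "Random Forest",
    "Neural Network",
    "AdaBoost",
    "Naive Bayes",
    "QDA",
    "SGD",
    "LDA",
)


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the 15 benchmark algorithms at default settings."""
    factories = {
        "Nearest Neighbours": lambda: KNeighborsClassifier(),
        "Linear SVM": lambda: SVC(kernel="linear", random_state=seed),
        "Polynomial SVM": lambda: SVC(kernel="poly", random_state=seed),
        "RBF SVM": lambda: SVC(random_state=seed),
        "Gaussian Process": lambda: GaussianProcessClassifier(random_state=seed),
        "Gradient Boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "Decision Tree": lambda: DecisionTreeClassifier(random_state=seed),
        "Extra Trees": lambda: ExtraTreesClassifier(random_state=seed),
        "Random Forest": lambda: RandomForestClassifier(random_state=seed),
        "Neural Network": lambda: MLPClassifier(random_state=seed),
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "Naive Bayes": lambda: GaussianNB(),
        "QDA": lambda: QuadraticDiscriminantAnalysis(),
        "SGD": lambda: SGDClassifier(random_state=seed),
        "LDA": lambda: LinearDiscriminantAnalysis(),
    }
    try:
        return factories[name]()
    except KeyError:
        raise ValueError(f"unknown classifier {name!r}") from None


@dataclass
class MetricSet:
    """One evaluation: proportions in [0, 1]; gap in [-1, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float | None = None
    train_test_gap: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "roc_auc": self.roc_auc, "train_test_gap": self.train_test_gap,
        }


def compute_metrics(y_true, y_pred, scores=None, classes=None) -> MetricSet:
    """Accuracy plus support-weighted precision/recall/f1 (and AUC).

    Weighted averaging makes accuracy identical to weighted recall, the
    pattern visible in reported benchmark tables.  `scores` (samples ×
    classes, column order = `classes`) enables the ROC AUC; without it
    the AUC is left unset.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty evaluation inputs")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    unknown = set(np.unique(y_pred)) - set(classes)
    unknown |= set(np.unique(y_true)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the known class set: {sorted(unknown)}")
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="weighted", zero_division=0)
    roc = None
    if scores is not None:
        roc = roc_auc_multiclass(y_true, scores, classes)
    return MetricSet(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision), recall=float(recall), f1=float(f1),
        roc_auc=roc,
    )


def roc_auc_multiclass(y_true, scores, classes=None) -> float:
    """Macro-averaged one-vs-rest ROC AUC.

    Each class's curve uses the unique score values as thresholds (the
    ``roc_curve`` default); classes absent from `y_true` are skipped
    with a warning.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    if scores.shape[1] != classes.size:
        raise ValueError("scores must have one column per class")
    aucs = []
    for j, cls in enumerate(classes):
        positive = y_true == cls
        if not positive.any() or positive.all():
            warnings.warn(f"class {cls!r} absent from one side of y_true; "
                          "skipped in ROC AUC")
            continue
        fpr, tpr, _ = roc_curve(positive.astype(int), scores[:, j])
        aucs.append(auc(fpr, tpr))
    if not aucs:
        raise ValueError("no class had both positive and negative samples")
    return float(np.mean(aucs))


def _class_scores(model, X: np.ndarray) -> np.ndarray | None:
    if hasattr(model, "predict_proba"):
        try:
            return np.asarray(model.predict_proba(X))
        except Exception:
            pass
    if hasattr(model, "decision_function"):
        s = np.asarray(model.decision_function(X))
        if s.ndim == 1:
            s = np.column_stack([-s, s])
        return s
    return None


@dataclass
class BenchResult:
    """Per-(classifier, seed) records plus per-classifier aggregates."""

    records: pd.DataFrame   # classifier, seed, split, metric columns
    seeds: list[int] = field(default_factory=list)

    def aggregates(self) -> pd.DataFrame:
        metrics = [c for c in self.records.columns
                   if c not in ("classifier", "seed")]
        g = self.records.groupby("classifier", sort=False)[metrics]
        out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=0)}, axis=1)
        out.columns = [f"{m}_{stat}" for stat, m in out.columns]
        return out.reset_index()

    def to_long(self) -> pd.DataFrame:
        value_cols = [c for c in self.records.columns
                      if c not in ("classifier", "seed")]
        long = self.records.melt(id_vars=["classifier", "seed"],
                                 value_vars=value_cols, var_name="metric",
                                 value_name="value")
        long[["split", "metric"]] = long["metric"].str.extract(
            r"^(train|test|cv)_(.+)$")
        return long[["classifier", "seed", "split", "metric", "value"]]


def compare_classifiers(X: FeatureMatrix, label: str = "class4",
                        seeds=10, folds: int = 10,
                        train_fraction: float = 0.80) -> BenchResult:
    """Run the 15-algorithm benchmark.

    `seeds` may be an integer n (seed list 0..n-1) or an explicit list;
    the result is deterministic given that list.  A classifier that
    fails on a given split is recorded as missing with a warning rather
    than aborting the benchmark.
    """
    seed_list = list(range(seeds)) if isinstance(seeds, int) else list(seeds)
    y = X.labels(label).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has fewer than 2 samples")
    Xv = X.features.to_numpy(dtype=float)

    rows = []
    for name in CLASSIFIER_NAMES:
        for seed in seed_list:
            X_tr, X_te, y_tr, y_te = train_test_split(
                Xv, y, train_size=train_fraction, random_state=seed,
                stratify=y)
            row = {"classifier": name, "seed": seed}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = make_classifier(name, seed)
                    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                                         random_state=seed)
                    cv_scores = cross_val_score(clone(model), X_tr, y_tr,
                                                cv=cv, scoring="accuracy")
                    model.fit(X_tr, y_tr)
                    train_m = compute_metrics(y_tr, model.predict(X_tr),
                                              _class_scores(model, X_tr),
                                              classes)
                    test_m = compute_metrics(y_te, model.predict(X_te),
                                             _class_scores(model, X_te),
                                             classes)
            except Exception as exc:  # degenerate input for this algorithm
                warnings.warn(f"{name} (seed {seed}) failed: {exc}")
                rows.append(row)
                continue
            gap = train_m.accuracy - test_m.accuracy
            row.update({"cv_accuracy": float(np.mean(cv_scores))})
            row.update({f"train_{k}": v for k, v in
                        train_m.as_dict().items() if v is not None})
            row.update({f"test_{k}": v for k, v in
                        test_m.as_dict().items() if v is not None})
            row["test_train_test_gap"] = gap
            rows.append(row)
    records = pd.DataFrame(rows)
    return BenchResult(records=records, seeds=seed_list)
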