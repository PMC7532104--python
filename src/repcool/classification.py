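"""Classifier families and cross-validated evaluation.

Five classifier families are supported — naive Bayes (NB), random forest
(RF), logistic regression (LR), decision tree (DT) and support vector
machine (SVM) — each with documented defaults (see ``make_classifier``).
Evaluation uses stratified k-fold cross-validation (tenfold by default):
per-fold confusion counts at a 0.5 score threshold, four derived metrics
(recall, precision, accuracy, F-measure) computed on the aggregate
counts, and a threshold-free AUC from the pooled out-of-fold scores
(per-fold AUCs are kept as well, since both conventions are in use).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .networks import ValidationError

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("NB", "RF", "LR", "DT", "SVM")


class ConfigurationError(ValueError):
    """Unknown classifier name or invalid evaluation settings."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


class Metrics(NamedTuple):
    recall: float
    precision: float
    accuracy: float
    f_measure: float


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Recall, precision, accuracy and F-measure from confusion counts.

    recall = TP/(TP+FN); precision = TP/(TP+FP);
    accuracy = (TP+TN)/total; F = 2·precision·recall/(precision+recall).
    A metric whose denominator is zero is undefined and reported as NaN
    with a warning — never silently zero.
    """
    if c.total == 0:
        raise ValidationError("empty evaluation: all confusion counts zero")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(
                f"{name} undefined (denominator zero); reporting NaN",
                stacklevel=3,
            )
            return math.nan
        return num / den

    recall = ratio(c.TP, c.TP + c.FN, "recall")
    precision = ratio(c.TP, c.TP + c.FP, "precision")
    accuracy = (c.TP + c.TN) / c.total
    if math.isnan(recall) or math.isnan(precision):
        f = math.nan
    elif precision + recall == 0:
        warnings.warn("F-measure undefined (precision+recall=0)", stacklevel=2)
        f = math.nan
    else:
        f = 2 * precision * recall / (precision + recall)
    return Metrics(recall, precision, accuracy, f)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(random positive outscores a random negative).

    Ties contribute 1/2; equals the trapezoidal area under the empirical
    ROC curve. Requires both classes present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise ValidationError("AUC requires scores from both classes")
    return float(roc_auc_score(labels, scores))


def make_classifier(name: str, seed: int = 0, standardize: bool = False,
                    **hyperparams):
    """Build a classifier handle exposing fit / predict_proba.

    Defaults per family: NB = Gaussian-likelihood naive Bayes; RF = 100
    trees, unlimited depth; LR = L2-penalized logistic regression; DT =
    CART tree with Gini impurity; SVM = RBF kernel with Platt-calibrated
    probability scores. ``standardize=True`` prepends per-column
    z-scoring (an extension useful for SVM/LR on raw counts; off by
    default). Stochastic families are seeded.
    """
    builders = {
        "NB": lambda: GaussianNB(**hyperparams),
        "RF": lambda: RandomForestClassifier(
            n_estimators=100, max_depth=None, random_state=seed,
            **hyperparams,
        ),
        "LR": lambda: LogisticRegression(
            max_iter=2000, random_state=seed, **hyperparams  # default L2
        ),
        "DT": lambda: DecisionTreeClassifier(
            criterion="gini", random_state=seed, **hyperparams
        ),
        "SVM": lambda: CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **hyperparams),
            method="sigmoid", cv=3, ensemble=False,
        ),
    }
    if name not in builders:
        raise ConfigurationError(
            f"unknown classifier {name!r}; valid names: "
            f"{', '.join(CLASSIFIER_NAMES)}"
        )
    model = builders[name]()
    if standardize:
        model = make_pipeline(StandardScaler(), model)
    return model


def positive_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probability scores from a fitted handle."""
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col]


@dataclass(frozen=True)
class EvaluationReport:
    """Cross-validation results for one classifier.

    ``aggregate`` is the element-wise sum of ``per_fold``; the four
    metrics are recomputed from it. ``auc`` pools out-of-fold scores into
    a single ranking (stabler at small n); ``per_fold_auc`` keeps the
    fold-wise alternative.
    """

    classifier_name: str
    n_folds: int
    seed: int
    per_fold: tuple[ConfusionCounts, ...]
    aggregate: ConfusionCounts
    recall: float
    precision: float
    accuracy: float
    f_measure: float
    auc: float
    per_fold_auc: tuple[float, ...] = field(default_factory=tuple)
    fold_assignment: tuple[int, ...] = field(default_factory=tuple)

    def summary(self) -> str:
        lines = [
            f"{self.classifier_name}: {self.n_folds}-fold cross-validation "
            f"(seed {self.seed}, n={self.aggregate.total})",
            f"  TP={self.aggregate.TP} TN={self.aggregate.TN} "
            f"FP={self.aggregate.FP} FN={self.aggregate.FN}",
            f"  recall={self.recall:.4f} precision={self.precision:.4f} "
            f"accuracy={self.accuracy:.4f} F={self.f_measure:.4f} "
            f"AUC={self.auc:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_fold": [
                {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}
                for c in self.per_fold
            ],
            "aggregate": {
                "TP": self.aggregate.TP,
                "TN": self.aggregate.TN,
                "FP": self.aggregate.FP,
                "FN": self.aggregate.FN,
            },
            "metrics": {
                "recall": self.recall,
                "precision": self.precision,
                "accuracy": self.accuracy,
                "f_measure": self.f_measure,
                "auc": self.auc,
            },
            "per_fold_auc": list(self.per_fold_auc),
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def cross_validate(
    matrix: FeatureMatrix,
    classifier,
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one classifier.

    Folds partition the rows (disjoint, exhaustive, class-stratified and
    a deterministic function of the row set, ``n_folds`` and ``seed``).
    The model is refit on each k−1 training split and scored on the
    held-out fold; confusion counts use a 0.5 threshold on the
    positive-class score, while AUC is computed threshold-free from the
    pooled out-of-fold scores.
    """
    if isinstance(classifier, str):
        classifier = make_classifier(classifier, seed=seed)
    X = np.asarray(matrix.X, dtype=float)
    y = matrix.y()
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValidationError(
            "cross-validation requires both positive and negative rows"
        )
    if n_folds < 2 or n_folds > counts.min():
        raise ConfigurationError(
            f"n_folds={n_folds} must be in [2, min class count="
            f"{counts.min()}]"
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold: list[ConfusionCounts] = []
    per_fold_auc: list[float] = []
    pooled_scores = np.empty(len(y), dtype=float)
    fold_of_row = np.empty(len(y), dtype=int)
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = clone(classifier)
        model.fit(X[train_idx], y[train_idx])
        scores = positive_scores(model, X[test_idx])
        pooled_scores[test_idx] = scores
        fold_of_row[test_idx] = k
        pred = (scores >= threshold).astype(int)
        yt = y[test_idx]
        per_fold.append(
            ConfusionCounts(
                TP=int(np.sum((pred == 1) & (yt == 1))),
                TN=int(np.sum((pred == 0) & (yt == 0))),
                FP=int(np.sum((pred == 1) & (yt == 0))),
                FN=int(np.sum((pred == 0) & (yt == 1))),
            )
        )
        if len(np.unique(yt)) == 2:
            per_fold_auc.append(compute_auc(scores, yt))
        else:  # pragma: no cover - stratification prevents this
            per_fold_auc.append(math.nan)

    aggregate = ConfusionCounts()
    for c in per_fold:
        aggregate = aggregate + c
    metrics = compute_metrics(aggregate)
    pooled_auc = compute_auc(pooled_scores, y)
    mean_fold_auc = float(np.nanmean(per_fold_auc))
    if abs(pooled_auc - mean_fold_auc) > 0.05:
        logger.info(
            "pooled AUC %.4f vs mean per-fold AUC %.4f differ by %.4f",
            pooled_auc, mean_fold_auc, abs(pooled_auc - mean_fold_auc),
        )
    name = getattr(classifier, "__class__", type(classifier)).__name__
    return EvaluationReport(
        classifier_name=name,
        n_folds=n_folds,
        seed=seed,
        per_fold=tuple(per_fold),
        aggregate=aggregate,
        recall=metrics.recall,
        precision=metrics.precision,
        accuracy=metrics.accuracy,
        f_measure=metrics.f_measure,
        auc=pooled_auc,
        per_fold_auc=tuple(per_fold_auc),
        fold_assignment=tuple(int(k) for k in fold_of_row),
    )


def evaluate_all(
    matrix: FeatureMatrix,
    n_folds: int = 10,
    seed: int = 0,
    names: Sequence[str] = CLASSIFIER_NAMES,
) -> dict[str, EvaluationReport]:
    """Cross-validate every classifier family on the same folds."""
    reports = {}
    for name in names:
        report = cross_validate(
            matrix, make_classifier(name, seed=seed),
            n_folds=n_folds, seed=seed,
        )
        reports[name] = EvaluationReport(
            **{**report.__dict__, "classifier_name": name}
        )
        logger.info("%s", reports[name].summary())
    return reports
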