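"""Confusion-matrix metrics, ROC/AUC, stratified cross-validation, consensus.

Metric conventions: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total, and G-mean = sqrt(sensitivity * specificity) — the
geometric mean of the two class-conditional accuracies, the balanced summary
of choice for heavily imbalanced screens. Percentages are reported to one
decimal place using round-half-even. A metric with an empty margin (no actives
or no inactives) is reported as undefined (None), never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def fp_rate(self) -> float:
        if self.fp + self.tn == 0:
            raise ValidationError("FP rate undefined: no true inactives")
        return self.fp / (self.fp + self.tn)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValidationError("label and prediction lengths differ")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricReport:
    """Derived metrics on [0, 1]; ``None`` marks an undefined ratio."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float
    g_mean: float | None
    auc: float | None = None

    def as_percent(self) -> dict:
        """Percentages to 1 d.p. (round-half-even); G-mean and AUC stay on [0,1]."""

        def pct(x):
            return None if x is None else round(100.0 * x, 1)

        return {
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "accuracy_pct": pct(self.accuracy),
            "g_mean": None if self.g_mean is None else round(self.g_mean, 2),
            "auc": None if self.auc is None else round(self.auc, 2),
        }


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricReport:
    """Sensitivity/specificity/accuracy/G-mean from a confusion matrix."""
    if cm.total <= 0:
        raise ValidationError("empty confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    acc = (cm.tp + cm.tn) / cm.total
    g = math.sqrt(sens * spec) if sens is not None and spec is not None else None
    return MetricReport(sensitivity=sens, specificity=spec, accuracy=acc, g_mean=g, auc=auc)


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and the trapezoidal AUC.

    The AUC equals the Mann-Whitney concordance probability with tied scores
    counted as half-concordant.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(roc_auc_score(labels, scores))


def stratified_folds(
    labels: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified fold indices; every fold must contain an active."""
    labels = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    n_active = int((labels == 1).sum())
    if n_active < folds:
        raise ValidationError(
            f"only {n_active} actives cannot be stratified into {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    learner_family: str,
    table,
    labels: Sequence[int],
    cost=None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[ConfusionMatrix, list[MetricReport], float]:
    """Stratified k-fold CV of one learner: pooled confusion matrix, per-fold
    reports, and the AUC over the pooled out-of-fold scores."""
    from .classify import CostMatrix, predict, train  # deferred: avoids an import cycle
    from .descriptors import DescriptorTable

    labels = np.asarray(labels, dtype=int)
    cost = cost or CostMatrix()
    pooled = ConfusionMatrix(0, 0, 0, 0)
    fold_reports = []
    oof_scores = np.empty(len(labels))
    for train_idx, test_idx in stratified_folds(labels, folds, seed):
        sub_train = DescriptorTable(
            [table.compound_ids[i] for i in train_idx], table.columns, table.values[train_idx]
        )
        sub_test = DescriptorTable(
            [table.compound_ids[i] for i in test_idx], table.columns, table.values[test_idx]
        )
        model = train(learner_family, sub_train, labels[train_idx], cost, seed)
        pred, scores = predict(model, sub_test)
        oof_scores[test_idx] = scores
        cm = ConfusionMatrix.from_predictions(labels[test_idx], pred)
        pooled = pooled + cm
        fold_reports.append(metrics(cm))
    _, auc = roc_auc(labels, oof_scores)
    return pooled, fold_reports, auc


def consensus(predictions: Sequence[Iterable[str]]) -> set[str]:
    """Compounds predicted active by every model (set intersection)."""
    if len(predictions) < 1:
        raise ValidationError("consensus requires at least one model")
    sets = [set(p) for p in predictions]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def write_metric_table(rows: dict[str, tuple[ConfusionMatrix, MetricReport]],
                       path: str | Path) -> None:
    """Tab-separated table in the conventional column order:
    model, TP, TN, FP, FN, Sn, Sp, Acc, G-mean."""
    lines = ["model\tTP\tTN\tFP\tFN\tsensitivity_pct\tspecificity_pct\taccuracy_pct\tg_mean"]
    for name, (cm, report) in rows.items():
        p = report.as_percent()
        lines.append(
            f"{name}\t{cm.tp}\t{cm.tn}\t{cm.fp}\t{cm.fn}\t"
            f"{p['sensitivity_pct']}\t{p['specificity_pct']}\t{p['accuracy_pct']}\t{p['g_mean']}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_metric_json(rows: dict[str, tuple[ConfusionMatrix, MetricReport]],
                      path: str | Path) -> None:
    payload = {}
    for name, (cm, report) in rows.items():
        payload[name] = {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}
        payload[name].update(report.as_percent())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_roc_csv(points: Sequence[tuple[float, float]], path: str | Path) -> None:
    Path(path).write_text(
        "fpr,tpr\n" + "".join(f"{x},{y}\n" for x, y in points)
    )
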