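"""Cost-sensitive classification of imbalanced bioassay data.

Three learner families are supported — a native naive Bayes, a random forest,
and a linear-SVM trained by sequential minimal optimisation-style solvers with
logistic score calibration. Cost sensitivity is realized uniformly by instance
reweighting: every active training row carries weight ``c_fn`` (the cost of a
false negative) while inactive rows carry weight 1, so raising ``c_fn``
penalizes missed actives across all families.

``tune_fn_cost`` implements the imbalance-handling policy of capping the
cross-validated false-positive rate: the FN cost is escalated (geometric
doubling, then integer bisection) and the largest cost whose CV FP rate stays
at or below the ceiling (default 20%) is retained.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .descriptors import DescriptorTable
from .errors import DegenerateDataError, ValidationError
from .evaluate import ConfusionMatrix, stratified_folds

LEARNER_FAMILIES = ("naive_bayes", "random_forest", "svm_smo_like")

_PERSIST_VERSION = 1
_MAX_COST = 2 ** 20


@dataclass(frozen=True)
class CostMatrix:
    """2x2 misclassification cost matrix; only the FN cost is tunable."""

    c_fn: float = 1.0
    c_fp: float = 1.0  # fixed reference cost
    c_tp: float = 0.0
    c_tn: float = 0.0

    def __post_init__(self):
        if self.c_fn < 1:
            raise ValidationError("c_fn must be >= 1")
        if self.c_fp != 1.0 or self.c_tp != 0.0 or self.c_tn != 0.0:
            raise ValidationError("only the FN cost is adjustable; c_fp is fixed at 1")

    def sample_weights(self, labels: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(labels) == 1, self.c_fn, 1.0)


class _NativeNaiveBayes:
    """Weighted naive Bayes: Bernoulli likelihoods for binary columns, Gaussian
    for continuous ones, Laplace smoothing alpha=1 on counts. Weighting a row by
    an integer w is exactly equivalent to replicating it w times."""

    def __init__(self, binary_mask: np.ndarray):
        self.binary_mask = binary_mask

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray):
        self.classes_ = np.array([0, 1])
        w = np.asarray(sample_weight, dtype=float)
        self.log_prior_ = np.empty(2)
        nb = int(self.binary_mask.sum())
        nc = X.shape[1] - nb
        self.bern_logp_ = np.empty((2, nb, 2))  # class x feature x {0,1}
        self.gauss_mean_ = np.empty((2, nc))
        self.gauss_var_ = np.empty((2, nc))
        Xb = X[:, self.binary_mask]
        Xc = X[:, ~self.binary_mask]
        total_w = w.sum()
        for cls in (0, 1):
            wc = w[y == cls]
            wsum = wc.sum()
            self.log_prior_[cls] = np.log(wsum / total_w)
            ones = (wc[:, None] * Xb[y == cls]).sum(axis=0)
            p1 = (ones + 1.0) / (wsum + 2.0)  # Laplace alpha=1
            self.bern_logp_[cls, :, 1] = np.log(p1)
            self.bern_logp_[cls, :, 0] = np.log(1.0 - p1)
            if nc:
                mu = (wc[:, None] * Xc[y == cls]).sum(axis=0) / wsum
                var = (wc[:, None] * (Xc[y == cls] - mu) ** 2).sum(axis=0) / wsum
                self.gauss_mean_[cls] = mu
                self.gauss_var_[cls] = np.maximum(var, 1e-9)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        Xb = X[:, self.binary_mask].astype(int)
        Xc = X[:, ~self.binary_mask]
        jll = np.tile(self.log_prior_, (X.shape[0], 1))
        for cls in (0, 1):
            jll[:, cls] += np.where(
                Xb == 1, self.bern_logp_[cls, :, 1], self.bern_logp_[cls, :, 0]
            ).sum(axis=1)
            if Xc.shape[1]:
                var = self.gauss_var_[cls]
                jll[:, cls] += (
                    -0.5 * np.log(2 * np.pi * var)
                    - 0.5 * (Xc - self.gauss_mean_[cls]) ** 2 / var
                ).sum(axis=1)
        return jll

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the active class."""
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        post = np.exp(jll)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


class _CalibratedLinearSVM:
    """Linear SVM (SMO-style dual problem) with a logistic model fitted on the
    decision values for calibrated activity scores."""

    def __init__(self, seed: int):
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray):
        self.svm_ = LinearSVC(random_state=self.seed)
        self.svm_.fit(X, y, sample_weight=sample_weight)
        d = self.svm_.decision_function(X).reshape(-1, 1)
        self.calibrator_ = LogisticRegression(random_state=self.seed)
        self.calibrator_.fit(d, y, sample_weight=sample_weight)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm_.predict(X).astype(int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        d = self.svm_.decision_function(X).reshape(-1, 1)
        return self.calibrator_.predict_proba(d)[:, 1]


@dataclass
class CostModel:
    """A fitted cost-sensitive classifier; scores are oriented so that higher
    means more likely active."""

    learner_family: str
    cost: CostMatrix
    column_names: list[str]
    fitted: object
    seed: int
    warning: str | None = None

    def save(self, path: str | Path) -> None:
        payload = {
            "version": _PERSIST_VERSION,
            "learner_family": self.learner_family,
            "cost": self.cost,
            "column_names": self.column_names,
            "fitted": self.fitted,
            "seed": self.seed,
            "warning": self.warning,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "CostModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != _PERSIST_VERSION:
            raise ValidationError(f"unsupported model file version in {path}")
        payload.pop("version")
        return cls(**payload)


def _check_training_inputs(table: DescriptorTable, labels: np.ndarray) -> None:
    if labels.shape[0] != len(table.compound_ids):
        raise ValidationError("labels length does not match table rows")
    if np.isnan(table.values).any():
        raise ValidationError("descriptor table contains missing values")
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("training set contains a single class")


def train(
    learner_family: str,
    table: DescriptorTable,
    labels: Sequence[int],
    cost: CostMatrix | None = None,
    seed: int = 0,
) -> CostModel:
    """Fit one learner family under the given cost matrix (deterministic per seed)."""
    if learner_family not in LEARNER_FAMILIES:
        raise ValidationError(f"unknown learner family {learner_family!r}")
    cost = cost or CostMatrix()
    labels = np.asarray(labels, dtype=int)
    _check_training_inputs(table, labels)
    X = table.values
    w = cost.sample_weights(labels)

    if learner_family == "naive_bayes":
        binary_mask = np.array([c.dtype == "binary" for c in table.columns])
        fitted = _NativeNaiveBayes(binary_mask).fit(X, labels, w)
    elif learner_family == "random_forest":
        fitted = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        fitted.fit(X, labels, sample_weight=w)
    else:
        fitted = _CalibratedLinearSVM(seed).fit(X, labels, w)

    return CostModel(
        learner_family=learner_family,
        cost=cost,
        column_names=table.column_names,
        fitted=fitted,
        seed=seed,
    )


def predict(model: CostModel, table: DescriptorTable) -> tuple[np.ndarray, np.ndarray]:
    """Predicted classes (1 = active) and real-valued activity scores per row."""
    if table.column_names != model.column_names:
        missing = sorted(set(model.column_names) - set(table.column_names))
        extra = sorted(set(table.column_names) - set(model.column_names))
        raise ValidationError(
            f"descriptor schema mismatch; missing columns: {missing}, extra: {extra}"
        )
    X = table.values
    fitted = model.fitted
    if isinstance(fitted, RandomForestClassifier):
        scores = fitted.predict_proba(X)[:, list(fitted.classes_).index(1)]
        classes = fitted.predict(X).astype(int)
    else:
        scores = fitted.predict_score(X)
        classes = fitted.predict(X)
    return classes, scores


def cv_confusion(
    learner_family: str,
    table: DescriptorTable,
    labels: np.ndarray,
    cost: CostMatrix,
    folds: int,
    seed: int,
) -> ConfusionMatrix:
    """Pooled confusion matrix over stratified CV folds for one cost setting."""
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for train_idx, test_idx in stratified_folds(labels, folds, seed):
        sub_train = DescriptorTable(
            [table.compound_ids[i] for i in train_idx], table.columns, table.values[train_idx]
        )
        sub_test = DescriptorTable(
            [table.compound_ids[i] for i in test_idx], table.columns, table.values[test_idx]
        )
        model = train(learner_family, sub_train, labels[train_idx], cost, seed)
        pred, _ = predict(model, sub_test)
        pooled = pooled + ConfusionMatrix.from_predictions(labels[test_idx], pred)
    return pooled


def tune_fn_cost(
    learner_family: str,
    table: DescriptorTable,
    labels: Sequence[int],
    fp_ceiling: float = 0.20,
    folds: int = 5,
    seed: int = 0,
) -> tuple[CostModel, float, ConfusionMatrix]:
    """Escalate the FN cost until the CV false-positive rate reaches the ceiling.

    Doubles ``c_fn`` from 1 until the pooled CV FP rate exceeds ``fp_ceiling``,
    then bisects down to a resolution of one cost unit, returning the largest
    integer cost whose FP rate stays at or below the ceiling, the model refit
    on all data at that cost, and the pooled CV confusion matrix. If the
    ceiling is already exceeded at ``c_fn`` = 1 the model is returned with a
    warning flag (ceiling unreachable from below).
    """
    if not 0.0 < fp_ceiling < 1.0:
        raise ValidationError("fp_ceiling must be in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    _check_training_inputs(table, labels)

    def fp_rate_at(c: float) -> tuple[float, ConfusionMatrix]:
        cm = cv_confusion(learner_family, table, labels, CostMatrix(c_fn=c), folds, seed)
        return cm.fp_rate, cm

    rate1, cm1 = fp_rate_at(1)
    if rate1 > fp_ceiling:
        model = train(learner_family, table, labels, CostMatrix(c_fn=1), seed)
        model.warning = (
            f"CV FP rate {rate1:.3f} exceeds the ceiling {fp_ceiling} already at c_fn=1"
        )
        return model, 1.0, cm1

    lo, cm_lo = 1, cm1
    hi = None
    tested = [(1, cm1)]
    c = 2
    while c <= _MAX_COST:
        rate, cm = fp_rate_at(c)
        if rate <= fp_ceiling:
            lo, cm_lo = c, cm
            tested.append((c, cm))
            c *= 2
        else:
            hi = c
            break
    if hi is None:
        # ceiling never crossed: escalation beyond the plateau buys nothing, so
        # return the smallest tested cost already at the final confusion matrix
        for c_small, cm_small in tested:
            if cm_small == cm_lo:
                return (
                    train(learner_family, table, labels, CostMatrix(c_fn=c_small), seed),
                    float(c_small),
                    cm_small,
                )
    if hi is not None:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            rate, cm = fp_rate_at(mid)
            if rate <= fp_ceiling:
                lo, cm_lo = mid, cm
            else:
                hi = mid
    model = train(learner_family, table, labels, CostMatrix(c_fn=lo), seed)
    return model, float(lo), cm_lo
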