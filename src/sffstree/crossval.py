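"""Leave-one-out and stratified k-fold evaluation of threshold trees.

The positive class is ``tumor`` throughout:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)

LOOCV runs n deterministic folds in sample order, retrains a tree on the
remaining n - 1 samples each time, and accumulates the held-out predictions;
its accuracy equals the mean of the n per-fold 0/1 outcomes. There is no
randomness anywhere in LOOCV. k-fold uses stratified folds (per-class counts
balanced to within one sample) whose assignment is a pure function of sample
order and the seed; ``k = n`` reduces exactly to LOOCV.

A training fold that loses one class entirely still proceeds — the tree
degenerates to a single majority leaf — and is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InsufficientDataError, UsageError, ValidationError
from .expr_io import POSITIVE_CLASS, ExpressionDataset
from .tree import TreeParams, fit_tree_matrix, predict_row

logger = logging.getLogger("sffstree")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(
        cls,
        truth: Sequence[str],
        predicted: Sequence[str],
        positive: str = POSITIVE_CLASS,
    ) -> "ConfusionMatrix":
        if len(truth) != len(predicted):
            raise UsageError("truth and predictions must align")
        tp = fp = fn = tn = 0
        for t, p in zip(truth, predicted):
            if t == positive:
                if p == positive:
                    tp += 1
                else:
                    fn += 1
            else:
                if p == positive:
                    fp += 1
                else:
                    tn += 1
        return cls(tp, fp, fn, tn)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


class Metrics(NamedTuple):
    """Derived proportions; a metric with zero denominator is ``None``."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def metrics(cm: ConfusionMatrix) -> Metrics:
    """sensitivity, specificity and accuracy of a confusion matrix."""
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    acc = (cm.tp + cm.tn) / cm.total if cm.total > 0 else None
    return Metrics(sens, spec, acc)


@dataclass
class CVResult:
    """Outcome of one cross-validation evaluation."""

    scheme: dict
    predictions: list[tuple[str, str, str]]  # (sample_id, true, predicted)
    confusion: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "predictions": [list(p) for p in self.predictions],
            "confusion": self.confusion.to_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CVResult":
        cm = ConfusionMatrix(**payload["confusion"])
        return cls(
            scheme=dict(payload["scheme"]),
            predictions=[tuple(p) for p in payload["predictions"]],
            confusion=cm,
            sensitivity=payload["sensitivity"],
            specificity=payload["specificity"],
            accuracy=payload["accuracy"],
            meta=dict(payload.get("meta", {})),
        )


def _result(scheme: dict, preds: list[tuple[str, str, str]], meta: dict) -> CVResult:
    cm = ConfusionMatrix.from_predictions(
        [p[1] for p in preds], [p[2] for p in preds]
    )
    m = metrics(cm)
    return CVResult(
        scheme=scheme,
        predictions=preds,
        confusion=cm,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        accuracy=m.accuracy,
        meta=meta,
    )


def _evaluate_folds(
    ds: ExpressionDataset,
    features: Sequence[str],
    params: TreeParams,
    folds: list[np.ndarray],
) -> list[tuple[str, str, str]]:
    """Train on the complement of each fold, predict its members."""
    x = ds.feature_matrix(features)  # samples x features
    labels = list(ds.labels)
    feature_index = {f: j for j, f in enumerate(features)}
    n = x.shape[0]
    preds: dict[int, str] = {}
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train_labels = [labels[i] for i in np.flatnonzero(mask)]
        if len(set(train_labels)) < 2:
            logger.warning(
                "training fold lost one class entirely; tree degenerates to "
                "a majority leaf"
            )
        t = fit_tree_matrix(x[mask], train_labels, list(features), params)
        for i in fold:
            preds[int(i)] = predict_row(t, x[i], feature_index)
    return [(ds.sample_ids[i], labels[i], preds[i]) for i in range(n)]


def loocv(
    ds: ExpressionDataset,
    features: Sequence[str],
    params: TreeParams = TreeParams(),
) -> CVResult:
    """Leave-one-out CV: n deterministic folds in sample order."""
    ds.require_two_classes()
    n = ds.n_samples
    if n < 3:
        raise InsufficientDataError("LOOCV needs >= 3 samples")
    if not features:
        raise UsageError("empty feature set")
    folds = [np.array([i]) for i in range(n)]
    preds = _evaluate_folds(ds, features, params, folds)
    return _result(
        {"scheme": "loocv"},
        preds,
        {"features": list(features), "params": params.to_dict()},
    )


def assign_folds(labels: Sequence[str], k: int, seed: int) -> np.ndarray:
    """Stratified fold index per sample; pure function of order and seed.

    Within each class (processed in sorted class order) samples are shuffled
    once with the seeded generator, then dealt round-robin continuing a
    global fold counter across classes — so per-class and total fold sizes
    each differ by at most one, and ``k = n`` yields singleton folds.
    """
    n = len(labels)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    counter = 0
    labels_arr = np.asarray(labels, dtype=object)
    for cls in sorted(set(labels)):
        members = np.flatnonzero(labels_arr == cls)
        order = rng.permutation(members.size)
        for j in order:
            fold_of[members[j]] = counter % k
            counter += 1
    return fold_of


def kfold(
    ds: ExpressionDataset,
    features: Sequence[str],
    params: TreeParams = TreeParams(),
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV; ``k = n`` reduces exactly to LOOCV."""
    ds.require_two_classes()
    n = ds.n_samples
    if k > n:
        raise UsageError(f"k={k} exceeds sample count n={n}")
    if k < 2:
        raise UsageError("k must be >= 2")
    if not features:
        raise UsageError("empty feature set")
    fold_of = assign_folds(ds.labels, k, seed)
    folds = [np.flatnonzero(fold_of == f) for f in range(k)]
    folds = [f for f in folds if f.size > 0]
    preds = _evaluate_folds(ds, features, params, folds)
    return _result(
        {"scheme": "kfold", "k": k, "seed": seed},
        preds,
        {"features": list(features), "params": params.to_dict()},
    )
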