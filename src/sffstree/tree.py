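"""C4.5-style decision trees on continuous expression features.

Induction follows the classic recipe for binary-class, continuous-attribute
data:

* splits are binary thresholds ``probe <= t`` / ``probe > t``, where ``t`` is
  always an attribute value observed at the node (candidates are every
  distinct observed value except the maximum; no midpoint interpolation);
* split quality is information gain by default (gain ratio by flag);
* growth stops at class purity, below ``2 * min_leaf`` samples, or when no
  split has positive gain; leaf labels follow the majority rule, ties
  resolved by the parent node's majority (lexicographically first class at a
  tied root);
* pruning is error-based subtree replacement (no subtree raising): a subtree
  collapses to its majority leaf when ``N * ucf(E, N)`` does not exceed the
  sum of ``n * ucf(e, n)`` over its leaves, where :func:`ucf` is the exact
  one-sided binomial upper confidence bound at the confidence factor
  (default 0.25) — not the historical normal approximation;
* each leaf maps to exactly one if-then rule whose conditions are the
  root-to-leaf path, rendered like ``If RUVBL1 > 7.523 then tumor (57/4)``.

Induction is fully deterministic: ties between equally scoring splits go to
the earlier feature in the caller's feature order, then the smaller
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats as _sstats

from .errors import DomainError, InputError, UsageError, ValidationError
from .expr_io import CLASSES, ExpressionDataset

#: gains at or below this are treated as zero (guards log2 rounding noise)
GAIN_EPS = 1e-12


@dataclass(frozen=True)
class TreeParams:
    """Induction and pruning knobs.

    confidence
        pruning confidence factor CF in (0, 1); smaller prunes harder.
    min_leaf
        minimum training samples per leaf.
    criterion
        ``info_gain`` (default) or ``gain_ratio``.
    prune
        whether :func:`fit_tree` applies error-based pruning after growth.
    """

    confidence: float = 0.25
    min_leaf: int = 2
    criterion: str = "info_gain"
    prune: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValidationError("confidence must lie strictly in (0, 1)")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")
        if self.criterion not in ("info_gain", "gain_ratio"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")

    def to_dict(self) -> dict:
        return {
            "confidence": self.confidence,
            "min_leaf": self.min_leaf,
            "criterion": self.criterion,
            "prune": self.prune,
        }


@dataclass(frozen=True)
class Leaf:
    label: str
    n_covered: int
    n_misclassified: int
    class_counts: tuple[int, int]


@dataclass(frozen=True)
class Internal:
    probe_id: str
    threshold: float
    left: "Node"
    right: "Node"
    majority: str
    class_counts: tuple[int, int]

    @property
    def n_covered(self) -> int:
        return sum(self.class_counts)


Node = Union[Leaf, Internal]


@dataclass(frozen=True)
class Condition:
    probe_id: str
    op: str  # "<=" or ">"
    threshold: float

    def __str__(self) -> str:
        return f"{self.probe_id} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """One leaf's if-then rule; conditions in root-to-leaf order."""

    conditions: tuple[Condition, ...]
    predicted_class: str
    n_covered: int
    n_misclassified: int

    def __init__(self, conditions, predicted_class, n_covered, n_misclassified):
        object.__setattr__(self, "conditions", tuple(conditions))
        object.__setattr__(self, "predicted_class", predicted_class)
        object.__setattr__(self, "n_covered", int(n_covered))
        object.__setattr__(self, "n_misclassified", int(n_misclassified))

    def matches(self, sample: Mapping[str, float]) -> bool:
        for c in self.conditions:
            try:
                v = sample[c.probe_id]
            except KeyError:
                raise InputError(f"sample lacks probe {c.probe_id!r}") from None
            if c.op == "<=" and not v <= c.threshold:
                return False
            if c.op == ">" and not v > c.threshold:
                return False
        return True

    def render(self) -> str:
        body = " and ".join(str(c) for c in self.conditions) or "always"
        return (
            f"If {body} then {self.predicted_class} "
            f"({self.n_covered}/{self.n_misclassified})"
        )


@dataclass
class DecisionTree:
    """A fitted threshold tree plus its training bookkeeping."""

    root: Node
    classes: tuple[str, str] = CLASSES
    n_training: int = 0

    # -- structure ---------------------------------------------------------

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def rec(node: Node) -> None:
            if isinstance(node, Leaf):
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def depth(self) -> int:
        def rec(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    def probes_used(self) -> list[str]:
        seen: list[str] = []

        def rec(node: Node) -> None:
            if isinstance(node, Internal):
                if node.probe_id not in seen:
                    seen.append(node.probe_id)
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return seen

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(node: Node) -> dict:
            if isinstance(node, Leaf):
                return {
                    "kind": "leaf",
                    "label": node.label,
                    "n_covered": node.n_covered,
                    "n_misclassified": node.n_misclassified,
                    "class_counts": list(node.class_counts),
                }
            return {
                "kind": "internal",
                "probe_id": node.probe_id,
                "threshold": node.threshold,
                "majority": node.majority,
                "class_counts": list(node.class_counts),
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "classes": list(self.classes),
            "n_training": self.n_training,
            "root": enc(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DecisionTree":
        def dec(d: dict) -> Node:
            if d["kind"] == "leaf":
                return Leaf(
                    d["label"],
                    int(d["n_covered"]),
                    int(d["n_misclassified"]),
                    tuple(d["class_counts"]),
                )
            return Internal(
                d["probe_id"],
                float(d["threshold"]),
                dec(d["left"]),
                dec(d["right"]),
                d["majority"],
                tuple(d["class_counts"]),
            )

        return cls(
            root=dec(payload["root"]),
            classes=tuple(payload["classes"]),
            n_training=int(payload["n_training"]),
        )


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------


def _entropy2(c0: int, c1: int) -> float:
    # shared arithmetic with the numba kernel in _fast.py: keep in sync
    n = c0 + c1
    h = 0.0
    if c0 > 0:
        p = c0 / n
        h -= p * math.log2(p)
    if c1 > 0:
        p = c1 / n
        h -= p * math.log2(p)
    return h


def entropy(class_counts: Sequence[int]) -> float:
    """Shannon entropy in bits of a two-class count pair."""
    if len(class_counts) != 2:
        raise DomainError("entropy expects a pair of class counts")
    c0, c1 = int(class_counts[0]), int(class_counts[1])
    if c0 < 0 or c1 < 0:
        raise DomainError("class counts must be nonnegative")
    if c0 + c1 == 0:
        raise DomainError("entropy undefined for an empty node")
    return _entropy2(c0, c1)


def _best_split01(
    values: np.ndarray,
    y01: np.ndarray,
    gain_ratio: bool,
    min_leaf: int,
) -> tuple[float, float] | None:
    """Core split scan over a single feature; labels already 0/1.

    Candidates are observed values in ascending order, excluding the maximum.
    Strictly-greater-score updates keep the smallest qualifying threshold on
    ties. Mirrors the numba kernel in ``_fast.py`` expression-for-expression.
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    v = values[order]
    lab = y01[order]
    c1_total = int(lab.sum())
    c0_total = n - c1_total
    if c0_total == 0 or c1_total == 0:
        return None
    hp = _entropy2(c0_total, c1_total)
    best_score = 0.0
    best_thr = math.nan
    found = False
    c0 = c1 = 0
    for i in range(n - 1):
        if lab[i] == 0:
            c0 += 1
        else:
            c1 += 1
        if v[i] == v[i + 1]:
            continue
        nl = i + 1
        nr = n - nl
        if nl < min_leaf or nr < min_leaf:
            continue
        gain = (
            hp
            - (nl / n) * _entropy2(c0, c1)
            - (nr / n) * _entropy2(c0_total - c0, c1_total - c1)
        )
        if gain <= GAIN_EPS:
            continue
        if gain_ratio:
            sh = _entropy2(nl, nr)
            score = gain / sh if sh > 0.0 else 0.0
        else:
            score = gain
        if score > best_score:
            best_score = score
            best_thr = float(v[i])
            found = True
    if not found:
        return None
    return best_thr, best_score


def best_split(
    values: Sequence[float],
    labels: Sequence[str],
    criterion: str = "info_gain",
    min_leaf: int = 1,
    classes: tuple[str, str] = CLASSES,
) -> tuple[float, float] | None:
    """Best binary threshold for one feature, or ``None``.

    Returns ``(threshold, score)`` maximizing the criterion over all observed
    candidate thresholds, or ``None`` when no split has positive score or
    every admissible split would leave a child below ``min_leaf``.
    """
    v = np.asarray(values, dtype=float)
    lab = list(labels)
    if v.ndim != 1 or v.size != len(lab):
        raise UsageError("values and labels must be equal-length 1-D sequences")
    if v.size < 2:
        raise UsageError("need >= 2 observations to split")
    if criterion not in ("info_gain", "gain_ratio"):
        raise UsageError(f"unknown criterion {criterion!r}")
    unknown = set(lab) - set(classes)
    if unknown:
        raise UsageError(f"labels outside {classes}: {sorted(unknown)}")
    y01 = np.array([0 if c == classes[0] else 1 for c in lab], dtype=np.uint8)
    return _best_split01(v, y01, criterion == "gain_ratio", min_leaf)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def grow_matrix(
    x: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    params: TreeParams = TreeParams(),
    classes: tuple[str, str] = CLASSES,
) -> DecisionTree:
    """Grow an unpruned tree on a samples x features matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(labels) or x.shape[1] != len(feature_names):
        raise UsageError("matrix shape must be (n_samples, n_features)")
    if len(feature_names) == 0:
        raise UsageError("empty feature set")
    y01 = np.array([0 if c == classes[0] else 1 for c in labels], dtype=np.uint8)
    gain_ratio = params.criterion == "gain_ratio"

    def build(idx: np.ndarray, parent_majority: int) -> Node:
        c1 = int(y01[idx].sum())
        c0 = idx.size - c1
        if c1 > c0:
            major = 1
        elif c0 > c1:
            major = 0
        else:
            major = parent_majority
        n = idx.size
        mis = n - (c1 if major == 1 else c0)

        def leaf() -> Leaf:
            return Leaf(classes[major], n, mis, (c0, c1))

        if c0 == 0 or c1 == 0 or n < 2 * params.min_leaf:
            return leaf()
        best: tuple[float, int, float] | None = None  # (score, feat, thr)
        for j in range(len(feature_names)):
            res = _best_split01(x[idx, j], y01[idx], gain_ratio, params.min_leaf)
            if res is None:
                continue
            thr, score = res
            if best is None or score > best[0]:
                best = (score, j, thr)
        if best is None:
            return leaf()
        _, j, thr = best
        mask = x[idx, j] <= thr
        left = build(idx[mask], major)
        right = build(idx[~mask], major)
        return Internal(feature_names[j], float(thr), left, right, classes[major], (c0, c1))

    root = build(np.arange(x.shape[0]), 0)
    return DecisionTree(root=root, classes=classes, n_training=x.shape[0])


def grow(
    ds: ExpressionDataset,
    features: Sequence[str],
    params: TreeParams = TreeParams(),
) -> DecisionTree:
    """Grow an unpruned tree on a dataset restricted to ``features``."""
    if not features:
        raise UsageError("empty feature set")
    x = ds.feature_matrix(features)
    return grow_matrix(x, ds.labels, list(features), params)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _ucf_cached(e: int, n: int, cf: float) -> float:
    if e >= n:
        return 1.0
    return float(_sstats.beta.ppf(1.0 - cf, e + 1, n - e))


def ucf(errors: int, n: int, confidence: float = 0.25) -> float:
    """Upper confidence bound on the true error rate of a leaf.

    The largest error probability ``p`` such that observing at most
    ``errors`` mistakes in ``n`` trials has tail probability ``confidence``:
    the solution of ``P(X <= E | N, p) = CF``, i.e. the ``1 - CF`` quantile
    of Beta(E + 1, N - E). Closed form at E = 0: ``1 - CF**(1/N)``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if errors < 0 or errors > n:
        raise DomainError("errors must lie in [0, n]")
    if not 0.0 < confidence < 1.0:
        raise DomainError("confidence must lie strictly in (0, 1)")
    return _ucf_cached(int(errors), int(n), float(confidence))


def prune(tree: DecisionTree, params: TreeParams = TreeParams()) -> DecisionTree:
    """Bottom-up error-based subtree replacement.

    A subtree is replaced by its majority leaf iff the leaf's pessimistic
    error count ``N * ucf(E, N)`` is at most the sum of the (already pruned)
    subtree leaves' ``n * ucf(e, n)``. Leaf counts are recomputed from the
    node's training counts. No subtree raising.
    """
    cf = params.confidence
    classes = tree.classes

    def rec(node: Node) -> tuple[Node, float]:
        if isinstance(node, Leaf):
            return node, node.n_covered * ucf(node.n_misclassified, node.n_covered, cf)
        left, lb = rec(node.left)
        right, rb = rec(node.right)
        c0, c1 = node.class_counts
        n = c0 + c1
        e = n - (c1 if node.majority == classes[1] else c0)
        leaf_bound = n * ucf(e, n, cf)
        child_bound = lb + rb
        if leaf_bound <= child_bound:
            return Leaf(node.majority, n, e, (c0, c1)), leaf_bound
        if left is node.left and right is node.right:
            return node, child_bound
        return (
            Internal(node.probe_id, node.threshold, left, right, node.majority, (c0, c1)),
            child_bound,
        )

    root, _ = rec(tree.root)
    return DecisionTree(root=root, classes=classes, n_training=tree.n_training)


def fit_tree(
    ds: ExpressionDataset,
    features: Sequence[str],
    params: TreeParams = TreeParams(),
) -> DecisionTree:
    """Grow and (by default) prune a tree on the full dataset."""
    t = grow(ds, features, params)
    return prune(t, params) if params.prune else t


def fit_tree_matrix(
    x: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    params: TreeParams = TreeParams(),
    classes: tuple[str, str] = CLASSES,
) -> DecisionTree:
    t = grow_matrix(x, labels, feature_names, params, classes)
    return prune(t, params) if params.prune else t


# ---------------------------------------------------------------------------
# prediction & rules
# ---------------------------------------------------------------------------


def predict(tree: DecisionTree, sample: Mapping[str, float]) -> str:
    """Deterministic root-to-leaf descent; ``<=`` goes left, ``>`` right."""
    node = tree.root
    while isinstance(node, Internal):
        try:
            v = sample[node.probe_id]
        except KeyError:
            raise InputError(f"sample lacks probe {node.probe_id!r}") from None
        node = node.left if v <= node.threshold else node.right
    return node.label


def predict_row(
    tree: DecisionTree, row: np.ndarray, feature_index: Mapping[str, int]
) -> str:
    """Descent on a dense feature row (internal fast path for CV loops)."""
    node = tree.root
    while isinstance(node, Internal):
        v = row[feature_index[node.probe_id]]
        node = node.left if v <= node.threshold else node.right
    return node.label


def extract_rules(tree: DecisionTree) -> list[Rule]:
    """One rule per leaf, conditions in root-to-leaf order (left first)."""
    rules: list[Rule] = []

    def rec(node: Node, conds: tuple[Condition, ...]) -> None:
        if isinstance(node, Leaf):
            rules.append(Rule(conds, node.label, node.n_covered, node.n_misclassified))
            return
        rec(node.left, conds + (Condition(node.probe_id, "<=", node.threshold),))
        rec(node.right, conds + (Condition(node.probe_id, ">", node.threshold),))

    rec(tree.root, ())
    return rules


def predict_by_rules(rules: Sequence[Rule], sample: Mapping[str, float]) -> str:
    """First-matching-rule evaluation (equivalent to tree descent)."""
    for rule in rules:
        if rule.matches(sample):
            return rule.predicted_class
    raise InputError("no rule matches the sample")
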