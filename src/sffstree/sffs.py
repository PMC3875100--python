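"""Sequential forward feature selection wrapped around tree LOOCV.

Starting from an empty probe set S, each iteration evaluates the LOOCV
accuracy of a decision tree trained on S plus each remaining candidate probe,
and appends the single best candidate (greedy search under the monotonicity
assumption). Accuracy ties are broken deterministically: smallest prefilter
adjusted p-value when available, then lexicographic probe id.

The search stops once accuracy has not strictly improved for ``patience``
consecutive iterations (default 2 — the empirical behavior of forward
selection on expression data, where two non-improving iterations follow the
last useful marker) or after ``max_iter`` iterations. The returned
``selected`` set is the shortest prefix of the chosen-probe sequence that
attains the best accuracy seen, so trailing non-improving picks are dropped.

Despite the traditional acronym, this is pure forward selection: there is no
floating/backtracking removal step.

The per-candidate LOOCV is executed by the compiled evaluator in
:mod:`sffstree._fast`, which is contract-tested to produce exactly the same
held-out predictions as :func:`sffstree.crossval.loocv`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._fast import loocv_predict, ucf_table
from .errors import InsufficientDataError, UsageError
from .expr_io import CLASSES, ExpressionDataset
from .tree import TreeParams

logger = logging.getLogger("sffstree")


@dataclass(frozen=True)
class SelectionStep:
    iteration: int
    n_candidates_evaluated: int
    chosen_probe: str
    loocv_accuracy_after: float
    improved: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    selected: list[str]
    params: dict = field(default_factory=dict)

    @property
    def best_accuracy(self) -> float:
        return max((s.loocv_accuracy_after for s in self.steps), default=math.nan)

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "iteration": s.iteration,
                    "n_candidates_evaluated": s.n_candidates_evaluated,
                    "chosen_probe": s.chosen_probe,
                    "loocv_accuracy_after": s.loocv_accuracy_after,
                    "improved": s.improved,
                }
                for s in self.steps
            ],
            "selected": list(self.selected),
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SelectionTrace":
        return cls(
            steps=[SelectionStep(**s) for s in payload["steps"]],
            selected=list(payload["selected"]),
            params=dict(payload.get("params", {})),
        )


def sffs_select(
    ds: ExpressionDataset,
    candidates: Sequence[str],
    params: TreeParams = TreeParams(),
    patience: int = 2,
    max_iter: int = 10,
    adj_p: Mapping[str, float] | None = None,
) -> SelectionTrace:
    """Greedy forward selection maximizing tree LOOCV accuracy.

    ``candidates`` is typically the prefilter's kept set but may be any probe
    list (duplicates are an error). ``adj_p`` feeds the tie-break; probes
    absent from it rank after probes present in it.
    """
    if not candidates:
        raise UsageError("empty candidate list")
    if len(set(candidates)) != len(candidates):
        raise UsageError("duplicate candidate probes")
    if patience < 1:
        raise UsageError("patience must be >= 1")
    if max_iter < 1:
        raise UsageError("max_iter must be >= 1")
    ds.require_two_classes()
    n = ds.n_samples
    if n < 3:
        raise InsufficientDataError("LOOCV needs >= 3 samples")

    x_all = ds.feature_matrix(candidates)  # samples x candidates
    y01 = np.array(
        [0 if c == CLASSES[0] else 1 for c in ds.labels], dtype=np.uint8
    )
    tab = ucf_table(n, params.confidence)
    gain_ratio = params.criterion == "gain_ratio"

    def tie_key(probe: str) -> tuple[float, str]:
        ap = math.inf
        if adj_p is not None and probe in adj_p:
            ap = float(adj_p[probe])
        return (ap, probe)

    remaining = list(range(len(candidates)))
    chosen_cols: list[int] = []
    steps: list[SelectionStep] = []
    best_acc = -math.inf
    no_improve = 0

    for iteration in range(1, max_iter + 1):
        if not remaining:
            break
        best_correct = -1
        best_col = -1
        best_key: tuple[float, str] | None = None
        for col in remaining:
            cols = chosen_cols + [col]
            sub = np.ascontiguousarray(x_all[:, cols])
            preds = loocv_predict(
                sub, y01, params.min_leaf, params.prune, gain_ratio, tab
            )
            correct = int(np.count_nonzero(preds == y01))
            if correct > best_correct:
                best_correct = correct
                best_col = col
                best_key = tie_key(candidates[col])
            elif correct == best_correct:
                key = tie_key(candidates[col])
                if key < best_key:
                    best_col = col
                    best_key = key
        acc = best_correct / n
        improved = acc > best_acc
        steps.append(
            SelectionStep(
                iteration=iteration,
                n_candidates_evaluated=len(remaining),
                chosen_probe=candidates[best_col],
                loocv_accuracy_after=acc,
                improved=improved,
            )
        )
        logger.info(
            "sffs iteration %d: chose %s (LOOCV accuracy %.4f%s)",
            iteration,
            candidates[best_col],
            acc,
            ", improved" if improved else "",
        )
        chosen_cols.append(best_col)
        remaining.remove(best_col)
        if improved:
            best_acc = acc
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= patience:
                break

    # shortest prefix attaining the maximum accuracy observed
    accs = [s.loocv_accuracy_after for s in steps]
    cut = accs.index(max(accs)) + 1 if accs else 0
    selected = [s.chosen_probe for s in steps[:cut]]

    return SelectionTrace(
        steps=steps,
        selected=selected,
        params={
            **params.to_dict(),
            "patience": patience,
            "max_iter": max_iter,
            "n_candidates": len(candidates),
        },
    )
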