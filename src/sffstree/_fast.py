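"""Compiled leave-one-out evaluator used by the selection wrapper.

The SFFS wrapper evaluates the LOOCV accuracy of a freshly induced tree for
every remaining candidate probe at every iteration — hundreds of thousands of
tiny tree fits on a realistic run. This module provides a numba kernel that
replicates the reference induction in :mod:`sffstree.tree` exactly:

* identical split scan (ascending observed thresholds, strictly-greater score
  updates, earlier feature wins ties),
* identical entropy/gain arithmetic (same expressions, same evaluation
  order),
* identical majority/tie and stopping rules,
* pruning against a precomputed table of the same exact-binomial ``ucf``
  values the reference uses.

Equality of predictions with :func:`sffstree.crossval.loocv` is asserted by
the test suite; any divergence there is a bug.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .tree import ucf

__all__ = ["ucf_table", "loocv_predict"]

_UCF_TABLES: dict[tuple[int, float], np.ndarray] = {}


def ucf_table(n_max: int, confidence: float) -> np.ndarray:
    """(E, N) -> ucf(E, N, confidence) lookup for all 0 <= E <= N <= n_max."""
    key = (int(n_max), float(confidence))
    tab = _UCF_TABLES.get(key)
    if tab is None:
        tab = np.zeros((n_max + 1, n_max + 1), dtype=np.float64)
        for n in range(1, n_max + 1):
            for e in range(n + 1):
                tab[e, n] = ucf(e, n, confidence)
        _UCF_TABLES[key] = tab
    return tab


@njit(cache=True)
def _entropy2(c0, c1):  # pragma: no cover - compiled
    n = c0 + c1
    h = 0.0
    if c0 > 0:
        p = c0 / n
        h -= p * math.log2(p)
    if c1 > 0:
        p = c1 / n
        h -= p * math.log2(p)
    return h


@njit(cache=True)
def _fit_and_predict(
    xtr, ytr, xte, min_leaf, do_prune, gain_ratio, ucf_tab
):  # pragma: no cover - compiled
    m, f = xtr.shape
    cap = 2 * m + 1
    feat = np.full(cap, -1, np.int64)
    thr = np.zeros(cap, np.float64)
    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    maj = np.zeros(cap, np.uint8)
    c0a = np.zeros(cap, np.int64)
    c1a = np.zeros(cap, np.int64)
    bound = np.zeros(cap, np.float64)

    idx = np.arange(m)
    tmp = np.empty(m, np.int64)
    vbuf = np.empty(m, np.float64)
    lbuf = np.empty(m, np.uint8)

    stack_node = np.empty(cap, np.int64)
    stack_lo = np.empty(cap, np.int64)
    stack_hi = np.empty(cap, np.int64)
    stack_pm = np.empty(cap, np.uint8)

    nnodes = 1
    sp = 0
    stack_node[sp] = 0
    stack_lo[sp] = 0
    stack_hi[sp] = m
    stack_pm[sp] = 0
    sp += 1

    while sp > 0:
        sp -= 1
        nd = stack_node[sp]
        lo = stack_lo[sp]
        hi = stack_hi[sp]
        pm = stack_pm[sp]

        c1 = 0
        for i in range(lo, hi):
            c1 += ytr[idx[i]]
        nn = hi - lo
        c0 = nn - c1
        if c1 > c0:
            mj = np.uint8(1)
        elif c0 > c1:
            mj = np.uint8(0)
        else:
            mj = pm
        maj[nd] = mj
        c0a[nd] = c0
        c1a[nd] = c1
        feat[nd] = -1

        if c0 == 0 or c1 == 0 or nn < 2 * min_leaf:
            continue

        hp = _entropy2(c0, c1)
        best_score = 0.0
        best_f = -1
        best_thr = 0.0
        for j in range(f):
            for i in range(nn):
                k = idx[lo + i]
                vbuf[i] = xtr[k, j]
                lbuf[i] = ytr[k]
            order = np.argsort(vbuf[:nn])
            cl0 = 0
            cl1 = 0
            for i in range(nn - 1):
                oi = order[i]
                if lbuf[oi] == 0:
                    cl0 += 1
                else:
                    cl1 += 1
                vi = vbuf[oi]
                if vi == vbuf[order[i + 1]]:
                    continue
                nl = i + 1
                nr = nn - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                gain = (
                    hp
                    - (nl / nn) * _entropy2(cl0, cl1)
                    - (nr / nn) * _entropy2(c0 - cl0, c1 - cl1)
                )
                if gain <= 1e-12:
                    continue
                if gain_ratio:
                    sh = _entropy2(nl, nr)
                    score = gain / sh if sh > 0.0 else 0.0
                else:
                    score = gain
                if score > best_score:
                    best_score = score
                    best_f = j
                    best_thr = vi
        if best_f < 0:
            continue

        p = 0
        for i in range(lo, hi):
            if xtr[idx[i], best_f] <= best_thr:
                tmp[p] = idx[i]
                p += 1
        q = p
        for i in range(lo, hi):
            if xtr[idx[i], best_f] > best_thr:
                tmp[q] = idx[i]
                q += 1
        for i in range(lo, hi):
            idx[i] = tmp[i - lo]

        lc = nnodes
        rc = nnodes + 1
        nnodes += 2
        feat[nd] = best_f
        thr[nd] = best_thr
        left[nd] = lc
        right[nd] = rc
        stack_node[sp] = lc
        stack_lo[sp] = lo
        stack_hi[sp] = lo + p
        stack_pm[sp] = mj
        sp += 1
        stack_node[sp] = rc
        stack_lo[sp] = lo + p
        stack_hi[sp] = hi
        stack_pm[sp] = mj
        sp += 1

    # bottom-up subtree replacement (children were created after parents)
    for nd in range(nnodes - 1, -1, -1):
        nn = c0a[nd] + c1a[nd]
        if maj[nd] == 1:
            e = nn - c1a[nd]
        else:
            e = nn - c0a[nd]
        leaf_bound = nn * ucf_tab[e, nn]
        if feat[nd] < 0:
            bound[nd] = leaf_bound
        else:
            child_bound = bound[left[nd]] + bound[right[nd]]
            if do_prune and leaf_bound <= child_bound:
                feat[nd] = -1
                bound[nd] = leaf_bound
            else:
                bound[nd] = child_bound

    nd = 0
    while feat[nd] >= 0:
        if xte[feat[nd]] <= thr[nd]:
            nd = left[nd]
        else:
            nd = right[nd]
    return maj[nd]


@njit(cache=True)
def _loocv_kernel(
    x, y, min_leaf, do_prune, gain_ratio, ucf_tab
):  # pragma: no cover - compiled
    n, f = x.shape
    preds = np.empty(n, np.uint8)
    xtr = np.empty((n - 1, f), np.float64)
    ytr = np.empty(n - 1, np.uint8)
    for hold in range(n):
        k = 0
        for i in range(n):
            if i == hold:
                continue
            for j in range(f):
                xtr[k, j] = x[i, j]
            ytr[k] = y[i]
            k += 1
        preds[hold] = _fit_and_predict(
            xtr, ytr, x[hold], min_leaf, do_prune, gain_ratio, ucf_tab
        )
    return preds


def loocv_predict(
    x: np.ndarray,
    y01: np.ndarray,
    min_leaf: int,
    do_prune: bool,
    gain_ratio: bool,
    ucf_tab: np.ndarray,
) -> np.ndarray:
    """Held-out 0/1 predictions for every LOOCV fold, in sample order."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y01 = np.ascontiguousarray(y01, dtype=np.uint8)
    return _loocv_kernel(
        x, y01, np.int64(min_leaf), bool(do_prune), bool(gain_ratio), ucf_tab
    )
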