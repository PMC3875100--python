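"""Per-probe differential expression and the overexpression prefilter.

For every probe an unpaired two-sample t-test (pooled-variance Student by
default, Welch by flag, paired available for matched tumor/normal designs)
compares tumor against normal log2 intensities; p-values are corrected with
the Benjamini-Hochberg step-up procedure. The prefilter keeps probes that are
both significant after correction (``adj_p < alpha``, strict; default alpha
0.001) and overexpressed in tumor — underexpressed probes are excluded
regardless of significance, since overexpressed transcripts are the ones
sought as diagnostic markers.

Note: this is an *ordinary* t-test. Empirical-Bayes variance moderation
(limma-style, as applied by GEO2R) is deliberately not reproduced; the gap is
logged whenever the prefilter runs.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError, UsageError
from .expr_io import ExpressionDataset

logger = logging.getLogger("sffstree")

Variant = Literal["pooled", "welch"]

#: default significance threshold on the BH-adjusted p-value
DEFAULT_ALPHA = 0.001


@dataclass(frozen=True)
class DiffExprRecord:
    """One probe's test summary."""

    probe_id: str
    mean_tumor: float
    mean_normal: float
    t_stat: float
    df: float
    p_value: float
    adj_p: float
    overexpressed: bool


class TTestResult(NamedTuple):
    t_stat: float
    df: float
    p_value: float


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: Variant = "pooled"
) -> TTestResult:
    """Two-sided two-sample t-test; positive t when mean(x) > mean(y).

    ``x`` is the tumor group by convention. ``variant='pooled'`` uses the
    equal-variance Student statistic (df = nx + ny - 2); ``'welch'`` the
    unequal-variance statistic with Welch-Satterthwaite df. When both groups
    have zero variance and equal means the statistic is defined as 0 with
    p = 1; zero variance with unequal means yields t = +/-inf, p = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise UsageError("expected 1-D sample vectors")
    nx, ny = xa.size, ya.size
    if nx < 2 or ny < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise DomainError("non-finite observation")
    if variant not in ("pooled", "welch"):
        raise UsageError(f"unknown t-test variant {variant!r}")

    mx, my = xa.mean(), ya.mean()
    vx = xa.var(ddof=1)
    vy = ya.var(ddof=1)
    if variant == "pooled":
        df = float(nx + ny - 2)
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        a, b = vx / nx, vy / ny
        se = math.sqrt(a + b)
        if a + b > 0:
            df = (a + b) ** 2 / (a * a / (nx - 1) + b * b / (ny - 1))
        else:
            df = float(nx + ny - 2)

    diff = mx - my
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Paired t-test on matched samples (x_i paired with y_i)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise UsageError("paired test requires equal-length groups")
    n = xa.size
    if n < 2:
        raise InsufficientDataError("paired test needs >= 2 pairs")
    d = xa - ya
    sd = d.std(ddof=1)
    df = float(n - 1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, d.mean()), df, 0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min over j with rank(j) >= rank(i) of min(1, p_(j) * n / rank(j))
    with ranks taken on ascending p.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise UsageError("expected a 1-D p-value vector")
    if arr.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized per-probe tests + the prefilter
# ---------------------------------------------------------------------------


def _t_rows(
    xt: np.ndarray, xn: np.ndarray, variant: Variant
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t over a probes x samples split (tumor vs normal)."""
    nx, ny = xt.shape[1], xn.shape[1]
    mx = xt.mean(axis=1)
    my = xn.mean(axis=1)
    vx = xt.var(axis=1, ddof=1)
    vy = xn.var(axis=1, ddof=1)
    if variant == "pooled":
        df = np.full(mx.shape, float(nx + ny - 2))
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        a, b = vx / nx, vy / ny
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
        df = np.where(a + b > 0, df, float(nx + ny - 2))
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0.0
    t = np.where(zero_se & (diff == 0.0), 0.0, t)
    t = np.where(zero_se & (diff != 0.0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_se & (diff == 0.0), 1.0, p)
    return t, df, p


def _t_rows_paired(xt: np.ndarray, xn: np.ndarray) -> tuple[np.ndarray, ...]:
    if xt.shape[1] != xn.shape[1]:
        raise UsageError("paired test requires equal class sizes")
    n = xt.shape[1]
    d = xt - xn
    md = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    df = np.full(md.shape, float(n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / (sd / math.sqrt(n))
    zero = sd == 0.0
    t = np.where(zero & (md == 0.0), 0.0, t)
    t = np.where(zero & (md != 0.0), np.sign(md) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero & (md == 0.0), 1.0, p)
    return t, df, p


def prefilter(
    ds: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
    variant: Variant = "pooled",
    paired: bool = False,
) -> tuple[list[DiffExprRecord], list[str]]:
    """Test every probe and keep the significant, tumor-overexpressed ones.

    Returns ``(records, kept)``: a :class:`DiffExprRecord` for *all* probes in
    input order, and the ids of probes with ``adj_p < alpha`` (strict) and
    ``mean_tumor > mean_normal``, preserving input probe order.
    """
    ds.require_two_classes()
    if not 0.0 < alpha <= 1.0:
        raise DomainError("alpha must lie in (0, 1]")
    tumor_cols = ds.class_columns("tumor")
    normal_cols = ds.class_columns("normal")
    if tumor_cols.size < 2 or normal_cols.size < 2:
        raise InsufficientDataError("each class needs >= 2 samples")
    logger.info(
        "prefilter: ordinary %s%s t-test per probe; moderated (limma-style) "
        "statistics are not applied",
        variant,
        " paired" if paired else "",
    )
    xt = ds.values[:, tumor_cols]
    xn = ds.values[:, normal_cols]
    if paired:
        t, df, p = _t_rows_paired(xt, xn)
    else:
        t, df, p = _t_rows(xt, xn, variant)
    adj = bh_adjust(p)
    mean_t = xt.mean(axis=1)
    mean_n = xn.mean(axis=1)
    records = [
        DiffExprRecord(
            probe_id=pid,
            mean_tumor=float(mean_t[i]),
            mean_normal=float(mean_n[i]),
            t_stat=float(t[i]),
            df=float(df[i]),
            p_value=float(p[i]),
            adj_p=float(adj[i]),
            overexpressed=bool(mean_t[i] > mean_n[i]),
        )
        for i, pid in enumerate(ds.probe_ids)
    ]
    kept = [r.probe_id for r in records if r.adj_p < alpha and r.overexpressed]
    logger.info("prefilter: kept %d / %d probes at alpha=%g", len(kept), len(records), alpha)
    return records, kept


def de_table(
    records: Sequence[DiffExprRecord], kept: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabular view of the records, optionally with a ``kept`` flag column."""
    df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "mean_tumor": [r.mean_tumor for r in records],
            "mean_normal": [r.mean_normal for r in records],
            "t_stat": [r.t_stat for r in records],
            "df": [r.df for r in records],
            "p_value": [r.p_value for r in records],
            "adj_p": [r.adj_p for r in records],
            "overexpressed": [r.overexpressed for r in records],
        }
    )
    if kept is not None:
        kept_set = set(kept)
        df["kept"] = df["probe_id"].isin(kept_set)
    return df


def read_de_tsv(path: str | os.PathLike) -> list[DiffExprRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DiffExprRecord(
            probe_id=str(row.probe_id),
            mean_tumor=float(row.mean_tumor),
            mean_normal=float(row.mean_normal),
            t_stat=float(row.t_stat),
            df=float(row.df),
            p_value=float(row.p_value),
            adj_p=float(row.adj_p),
            overexpressed=bool(row.overexpressed),
        )
        for row in df.itertuples(index=False)
    ]
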