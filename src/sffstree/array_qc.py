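"""Spot- and array-level qualification of two-color/one-color arrays.

Implements the detection and quality rules used before any statistics are run:

* **Present flag** — a spot is detected when its foreground median intensity
  reaches the background median plus three background standard deviations.
* **Basic QC** — three per-array parameters (percentage of Present spots, mean
  intensity of Present spots, CV of control-spot intensities) are compared
  across all arrays; an array is excluded when at least two of its parameters
  fall outside the Tukey fences [Q1 - 1.5*IQR, Q3 + 1.5*IQR]. A single
  outlying parameter is tolerated.
* **Reproducibility** — repeated arrays of the same sample pass when their
  Pearson correlation exceeds 0.95 and the "2-fold percentage" (share of
  probes whose raw-scale ratio exceeds 2-fold in either direction) is below
  15%. Both inequalities are strict.
* **Present-union filter** — a probe enters downstream analysis when it is
  Present on at least one qualified array.

Quartiles use linear interpolation between order statistics. The density-plot
("diagram") inspection step has no quantitative criterion and is supported as
a data export only (:func:`intensity_histogram`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DomainError,
    FormatError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)

#: names of the three basic-QC parameters, in report order
QC_PARAMS = ("pct_present", "mean_present_intensity", "control_cv")


@dataclass(frozen=True)
class SpotStats:
    """Per-spot scanner statistics (532 nm channel)."""

    spot_id: str
    fg_median: float
    bg_median: float
    bg_sd: float

    def __post_init__(self) -> None:
        if self.fg_median < 0 or self.bg_median < 0:
            raise ValidationError(f"spot {self.spot_id!r}: negative intensity")
        if self.bg_sd < 0:
            raise ValidationError(f"spot {self.spot_id!r}: negative background sd")


@dataclass
class ArrayQCReport:
    """Per-array summary used by :func:`basic_qc`."""

    array_id: str
    pct_present: float
    mean_present_intensity: float
    control_cv: float
    basic_pass: bool | None = None
    outlier_params: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_present <= 100.0:
            raise ValidationError("pct_present must lie in [0, 100]")
        if self.control_cv < 0:
            raise ValidationError("control_cv must be nonnegative")


def present_flag(spot: SpotStats) -> bool:
    """Detection call: foreground >= background median + 3 * background SD."""
    return spot.fg_median >= spot.bg_median + 3.0 * spot.bg_sd


def array_report(
    array_id: str,
    spots: Sequence[SpotStats],
    is_control: Sequence[bool],
) -> ArrayQCReport:
    """Summarize one array's spots into the three basic-QC parameters.

    The mean Present intensity uses the raw foreground median (no background
    subtraction); the choice is recorded in the report meta.
    """
    if len(spots) != len(is_control):
        raise ValidationError("is_control must align with spots")
    if not spots:
        raise InsufficientDataError(f"array {array_id!r} has no spots")
    present = np.array([present_flag(s) for s in spots], dtype=bool)
    fg = np.array([s.fg_median for s in spots], dtype=float)
    ctrl = np.asarray(is_control, dtype=bool)
    pct_present = 100.0 * present.mean()
    mean_present = float(fg[present].mean()) if present.any() else 0.0
    if not ctrl.any():
        raise InsufficientDataError(f"array {array_id!r} has no control spots")
    ctrl_int = fg[ctrl]
    mean_ctrl = ctrl_int.mean()
    if mean_ctrl <= 0:
        raise DomainError(f"array {array_id!r}: control mean intensity is 0")
    control_cv = float(ctrl_int.std(ddof=1) / mean_ctrl) if ctrl_int.size > 1 else 0.0
    return ArrayQCReport(
        array_id=array_id,
        pct_present=float(pct_present),
        mean_present_intensity=mean_present,
        control_cv=control_cv,
        meta={"present_intensity": "raw fg_median, no background subtraction"},
    )


def basic_qc(reports: Sequence[ArrayQCReport]) -> list[ArrayQCReport]:
    """Fill ``basic_pass`` across a batch of arrays.

    For each of the three parameters the acceptance interval is
    ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` over all arrays (linear-interpolation
    quartiles). An array fails iff two or more of its parameters fall outside
    their intervals. Order-invariant; returns new report objects.
    """
    if len(reports) < 4:
        raise InsufficientDataError(
            f"basic_qc needs >= 4 arrays for meaningful quartiles, got {len(reports)}"
        )
    table = {
        p: np.array([getattr(r, p) for r in reports], dtype=float) for p in QC_PARAMS
    }
    fences = {}
    for p, vals in table.items():
        q1, q3 = np.percentile(vals, [25.0, 75.0], method="linear")
        iqr = q3 - q1
        fences[p] = (q1 - 1.5 * iqr, q3 + 1.5 * iqr)
    out = []
    for r in reports:
        outliers = [
            p
            for p in QC_PARAMS
            if not (fences[p][0] <= getattr(r, p) <= fences[p][1])
        ]
        out.append(
            replace(r, basic_pass=len(outliers) < 2, outlier_params=outliers)
        )
    return out


class ReproducibilityResult(NamedTuple):
    pearson_r: float
    two_fold_pct: float
    passed: bool


def reproducibility_check(
    a: Sequence[float], b: Sequence[float]
) -> ReproducibilityResult:
    """Replicate-array agreement on raw-scale intensities.

    ``two_fold_pct`` counts probes whose ratio exceeds 2-fold in either
    direction (ratio > 2 or < 1/2). Pass requires r > 0.95 and
    two_fold_pct < 15, both strict.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 probes for a reproducibility check")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite intensity")
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("raw-scale intensities must be positive")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a zero-variance vector")
    r = float(stats.pearsonr(x, y).statistic)
    ratio = x / y
    n_two_fold = int(np.count_nonzero((ratio > 2.0) | (ratio < 0.5)))
    pct = 100.0 * n_two_fold / x.size
    return ReproducibilityResult(r, pct, r > 0.95 and pct < 15.0)


def present_union_filter(
    masks: Mapping[str, Mapping[str, bool]] | pd.DataFrame,
) -> "pd.Series":
    """Probe inclusion mask: Present on at least one qualified array.

    ``masks`` maps array id -> (probe id -> Present flag), or is a boolean
    probes x arrays DataFrame. All arrays must share the same probe universe.
    Returns a boolean Series indexed by probe id (order of the first array).
    """
    if isinstance(masks, pd.DataFrame):
        frame = masks.astype(bool)
        if frame.index.has_duplicates:
            raise AlignmentError("duplicate probe ids in mask index")
    else:
        if not masks:
            raise InsufficientDataError("no arrays supplied")
        series = {}
        universe: list[str] | None = None
        for array_id, mask in masks.items():
            probes = list(mask.keys() if isinstance(mask, dict) else mask.index)
            if universe is None:
                universe = probes
            elif set(probes) != set(universe):
                raise AlignmentError(
                    f"array {array_id!r} has a different probe universe"
                )
            s = pd.Series(mask, dtype=bool)
            series[array_id] = s.reindex(universe)
        frame = pd.DataFrame(series)
    return frame.any(axis=1)


def intensity_histogram(
    spots: Sequence[SpotStats], bins: int = 50
) -> pd.DataFrame:
    """Per-array intensity histogram table for the visual "diagram" step.

    Log2 of (1 + raw fg_median) against fixed-width bins; exported for
    inspection, never an automated pass/fail.
    """
    fg = np.array([s.fg_median for s in spots], dtype=float)
    log_int = np.log2(1.0 + fg)
    counts, edges = np.histogram(log_int, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def read_spot_stats_tsv(path: str | os.PathLike) -> list[SpotStats]:
    """Read one array's spot table (spot_id, fg_median, bg_median, bg_sd).

    An optional fifth column ``is_control`` (0/1) is returned alongside via
    :func:`read_spot_stats_tsv_with_controls`; this reader ignores it.
    """
    spots, _ = read_spot_stats_tsv_with_controls(path)
    return spots


def read_spot_stats_tsv_with_controls(
    path: str | os.PathLike,
) -> tuple[list[SpotStats], list[bool]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty spot table")
    header = [h.strip() for h in lines[0].split("\t")]
    required = ["spot_id", "fg_median", "bg_median", "bg_sd"]
    if header[: len(required)] != required:
        raise FormatError(f"{path}: expected columns {required}, got {header}")
    has_ctrl = len(header) > 4 and header[4] == "is_control"
    spots: list[SpotStats] = []
    controls: list[bool] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"{path}: line {lineno}: too few fields")
        try:
            spot = SpotStats(
                spot_id=parts[0].strip(),
                fg_median=float(parts[1]),
                bg_median=float(parts[2]),
                bg_sd=float(parts[3]),
            )
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric field") from None
        spots.append(spot)
        controls.append(bool(int(parts[4])) if has_ctrl and len(parts) > 4 else False)
    return spots, controls
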