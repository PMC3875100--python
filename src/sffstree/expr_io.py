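"""Expression-matrix and artifact I/O.

The canonical in-memory currency of the pipeline is :class:`ExpressionDataset`:
a probes x samples matrix of log2-scale intensities with exactly two sample
classes, ``tumor`` and ``normal`` (``tumor`` is the positive class throughout).

Readers exist for two plain-text formats:

* a tab-delimited matrix (first row: sample ids, first column: probe ids), and
* the GEO series-matrix format (the table block between its begin/end markers).

Values are assumed to be log2-transformed already; ``log2=True`` applies the
transform at load time. Missing cells are rejected by default and may instead
be imputed with the probe's per-class mean (``impute_missing=True``). Matrix
orientation is fixed as probes x samples and never auto-detected.

The module also serializes every downstream artifact (trees, rules, selection
traces, cross-validation results, differential-expression tables) to JSON or
TSV, losslessly for all declared fields.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    FormatError,
    LabelError,
    ParseError,
    UsageError,
    ValidationError,
)

logger = logging.getLogger("sffstree")

#: the two admissible sample classes, in canonical (lexicographic) order
CLASSES: tuple[str, str] = ("normal", "tumor")
#: positive class for sensitivity/specificity
POSITIVE_CLASS = "tumor"

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


# ---------------------------------------------------------------------------
# ExpressionDataset
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Labeled probes x samples log2-intensity matrix.

    Invariants (checked at construction): identifier uniqueness, shape
    agreement, finite values, labels drawn from :data:`CLASSES`. Presence of
    both classes is *not* required here — degenerate single-class datasets are
    legal inputs for e.g. pure-node tree fixtures — but every operation that
    trains or tests calls :meth:`require_two_classes` first.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    values: np.ndarray
    gene_symbols: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(c) for c in self.labels]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D probes x samples matrix")
        n_probes, n_samples = self.values.shape
        if n_probes != len(self.probe_ids):
            raise ValidationError(
                f"row count {n_probes} != number of probe ids {len(self.probe_ids)}"
            )
        if n_samples != len(self.sample_ids):
            raise ValidationError(
                f"column count {n_samples} != number of sample ids {len(self.sample_ids)}"
            )
        if len(self.labels) != len(self.sample_ids):
            raise ValidationError("one class label required per sample")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise LabelError(
                f"labels must be in {set(CLASSES)}; found {sorted(bad)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in expression matrix")
        if self.gene_symbols is not None:
            unknown = set(self.gene_symbols) - set(self.probe_ids)
            if unknown:
                raise ValidationError(
                    f"gene_symbols refer to unknown probes: {sorted(unknown)[:5]}"
                )

    # -- shape -------------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    # -- access ------------------------------------------------------------

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_lookup[probe_id]
        except AttributeError:
            self._probe_lookup = {p: i for i, p in enumerate(self.probe_ids)}
            return self.probe_index(probe_id)
        except KeyError:
            raise UsageError(f"unknown probe id: {probe_id!r}") from None

    def class_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples with the given class label."""
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == label)

    def feature_matrix(self, probe_ids: Sequence[str]) -> np.ndarray:
        """samples x features matrix for the given probes (in given order)."""
        rows = [self.probe_index(p) for p in probe_ids]
        return np.ascontiguousarray(self.values[rows, :].T)

    def sample_map(self, i: int) -> dict[str, float]:
        """Probe -> value mapping for sample column ``i`` (for prediction)."""
        col = self.values[:, i]
        return {p: float(col[j]) for j, p in enumerate(self.probe_ids)}

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = list(indices)
        return ExpressionDataset(
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            values=self.values[:, idx].copy(),
            gene_symbols=dict(self.gene_symbols) if self.gene_symbols else None,
            meta=dict(self.meta),
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionDataset":
        rows = [self.probe_index(p) for p in probe_ids]
        symbols = None
        if self.gene_symbols:
            symbols = {p: self.gene_symbols[p] for p in probe_ids if p in self.gene_symbols}
        return ExpressionDataset(
            probe_ids=list(probe_ids),
            sample_ids=list(self.sample_ids),
            labels=list(self.labels),
            values=self.values[rows, :].copy(),
            gene_symbols=symbols,
            meta=dict(self.meta),
        )

    def require_two_classes(self) -> None:
        if len(self.classes) < 2:
            raise LabelError(
                f"both classes required; dataset has only {self.classes}"
            )


# ---------------------------------------------------------------------------
# matrix readers
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


def _assemble_dataset(
    probe_ids: list[str],
    sample_ids: list[str],
    cells: list[list[str]],
    label_spec: Mapping[str, str],
    *,
    log2: bool = False,
    impute_missing: bool = False,
    meta: dict | None = None,
) -> ExpressionDataset:
    """Shared tail of both readers: parse cells, resolve labels, build."""
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample ids in header")
    if len(set(probe_ids)) != len(probe_ids):
        dup = [p for p in probe_ids if probe_ids.count(p) > 1]
        raise FormatError(f"duplicate probe id {dup[0]!r}")

    n_probes, n_samples = len(probe_ids), len(sample_ids)
    values = np.empty((n_probes, n_samples), dtype=np.float64)
    missing: list[tuple[int, int]] = []
    for i in range(n_probes):
        row = cells[i]
        for j in range(n_samples):
            raw = row[j].strip().strip('"')
            if raw.lower() in _MISSING_TOKENS:
                if impute_missing:
                    values[i, j] = np.nan
                    missing.append((i, j))
                    continue
                raise ParseError(
                    f"blank/missing cell at probe {probe_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {raw!r} at probe {probe_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None

    try:
        labels = [str(label_spec[s]) for s in sample_ids]
    except KeyError as exc:
        raise LabelError(f"label_spec missing sample {exc.args[0]!r}") from None

    if missing:
        _impute_per_class_mean(values, labels, missing, probe_ids)

    if log2:
        if np.any(values <= 0):
            raise DomainError("log2 transform requires strictly positive values")
        values = np.log2(values)

    return ExpressionDataset(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        labels=labels,
        values=values,
        meta=dict(meta or {}),
    )


def _impute_per_class_mean(
    values: np.ndarray,
    labels: list[str],
    missing: list[tuple[int, int]],
    probe_ids: list[str],
) -> None:
    labels_arr = np.asarray(labels, dtype=object)
    for i, j in missing:
        cols = np.flatnonzero(labels_arr == labels[j])
        peers = values[i, cols]
        peers = peers[np.isfinite(peers)]
        if peers.size == 0:
            raise ParseError(
                f"cannot impute probe {probe_ids[i]!r}: no observed value "
                f"in class {labels[j]!r}"
            )
        values[i, j] = float(peers.mean())


def read_expression_tsv(
    path: str | os.PathLike,
    label_spec: Mapping[str, str],
    *,
    log2: bool = False,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Read a tab-delimited probes x samples matrix.

    First row: sample ids (the first header cell names the probe column and is
    ignored). First column: probe ids. Remaining cells: numeric log2
    intensities. ``label_spec`` maps every sample id to ``tumor``/``normal``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    if not sample_ids:
        raise FormatError(f"{path}: header row has no sample ids")
    probe_ids: list[str] = []
    cells: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}: line {lineno} has {len(parts)} fields, "
                f"expected {len(header)}"
            )
        probe_ids.append(parts[0].strip().strip('"'))
        cells.append(parts[1:])
    return _assemble_dataset(
        probe_ids,
        sample_ids,
        cells,
        label_spec,
        log2=log2,
        impute_missing=impute_missing,
        meta={"source": str(path), "format": "tsv", "log2_applied": log2},
    )


def write_expression_tsv(ds: ExpressionDataset, path: str | os.PathLike) -> None:
    """Write the matrix as tab-delimited text (lossless to 17 sig. digits)."""
    df = pd.DataFrame(ds.values, index=ds.probe_ids, columns=ds.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


SERIES_TABLE_BEGIN = "!series_matrix_table_begin"
SERIES_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(
    path: str | os.PathLike,
    label_spec: Mapping[str, str],
    *,
    log2: bool = False,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Read the table block of a GEO series-matrix file.

    Everything between the standard begin/end marker lines is parsed as a
    tab-delimited table (first row ``ID_REF`` + sample ids, cells optionally
    double-quoted). All ``!``-prefixed header lines preceding the table are
    preserved verbatim in ``meta['series_matrix_header']``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        token = line.strip().lower()
        if token == SERIES_TABLE_BEGIN and begin is None:
            begin = i
        elif token == SERIES_TABLE_END and end is None:
            end = i
    if begin is None:
        raise FormatError(f"{path}: missing {SERIES_TABLE_BEGIN!r} marker")
    if end is None or end <= begin:
        raise FormatError(f"{path}: missing {SERIES_TABLE_END!r} marker")

    header_lines = [l for l in lines[:begin] if l.startswith("!")]
    table = [line for line in lines[begin + 1 : end] if line.strip()]
    if not table:
        raise FormatError(f"{path}: empty series-matrix table block")
    rows = [line.split("\t") for line in table]
    width = len(rows[0])
    for k, row in enumerate(rows):
        if len(row) != width:
            raise ParseError(
                f"{path}: ragged series-matrix table at block row {k + 1} "
                f"({len(row)} fields, expected {width})"
            )
    sample_ids = [c.strip().strip('"') for c in rows[0][1:]]
    probe_ids = [r[0].strip().strip('"') for r in rows[1:]]
    cells = [r[1:] for r in rows[1:]]
    return _assemble_dataset(
        probe_ids,
        sample_ids,
        cells,
        label_spec,
        log2=log2,
        impute_missing=impute_missing,
        meta={
            "source": str(path),
            "format": "series_matrix",
            "log2_applied": log2,
            "series_matrix_header": header_lines,
        },
    )


# ---------------------------------------------------------------------------
# label tables (sample_id <TAB> label), used by the CLI
# ---------------------------------------------------------------------------


def read_labels_tsv(path: str | os.PathLike) -> dict[str, str]:
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 'sample<TAB>label'")
        sample, label = parts[0].strip(), parts[1].strip()
        if sample in labels:
            raise FormatError(f"{path}: duplicate sample id {sample!r}")
        labels[sample] = label
    return labels


def write_labels_tsv(labels: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# artifact serialization
# ---------------------------------------------------------------------------

_COND_RE = re.compile(r"^(?P<probe>.+?)\s*(?P<op><=|>)\s*(?P<thr>[^\s].*)$")


def write_artifact(obj, path: str | os.PathLike, format: str | None = None) -> None:
    """Serialize any declared pipeline artifact.

    JSON for :class:`~sffstree.tree.DecisionTree`,
    :class:`~sffstree.sffs.SelectionTrace` and
    :class:`~sffstree.crossval.CVResult`; TSV for rule lists and
    differential-expression record lists; TSV matrix for
    :class:`ExpressionDataset`. ``format`` defaults to the path extension.
    """
    from . import crossval, diffexpr, sffs, tree  # local: avoid import cycles

    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "json"

    if isinstance(obj, ExpressionDataset):
        if format != "tsv":
            raise UsageError("ExpressionDataset serializes to tsv only")
        write_expression_tsv(obj, path)
        return
    if isinstance(obj, tree.DecisionTree):
        _dump_json({"artifact": "decision_tree", **obj.to_dict()}, path)
        return
    if isinstance(obj, sffs.SelectionTrace):
        _dump_json({"artifact": "selection_trace", **obj.to_dict()}, path)
        return
    if isinstance(obj, crossval.CVResult):
        _dump_json({"artifact": "cv_result", **obj.to_dict()}, path)
        return
    if isinstance(obj, (list, tuple)) and obj and all(
        isinstance(r, tree.Rule) for r in obj
    ):
        _write_rules_tsv(list(obj), path)
        return
    if isinstance(obj, (list, tuple)) and obj and all(
        isinstance(r, diffexpr.DiffExprRecord) for r in obj
    ):
        diffexpr.de_table(list(obj)).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
        return
    raise UsageError(f"unsupported artifact type: {type(obj).__name__}")


def read_artifact(path: str | os.PathLike, kind: str | None = None):
    """Inverse of :func:`write_artifact` for JSON artifacts and rule TSVs.

    ``kind`` (``tree``/``trace``/``cv``/``rules``/``de``) may be omitted for
    JSON files, which are self-describing via their ``artifact`` field.
    """
    from . import crossval, diffexpr, sffs, tree

    path = Path(path)
    if kind in (None, "tree", "trace", "cv") and path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        artifact = payload.get("artifact")
        if artifact == "decision_tree":
            return tree.DecisionTree.from_dict(payload)
        if artifact == "selection_trace":
            return sffs.SelectionTrace.from_dict(payload)
        if artifact == "cv_result":
            return crossval.CVResult.from_dict(payload)
        raise FormatError(f"{path}: unknown artifact type {artifact!r}")
    if kind == "rules":
        return _read_rules_tsv(path)
    if kind == "de":
        return diffexpr.read_de_tsv(path)
    raise UsageError(f"cannot read artifact of kind {kind!r} from {path}")


def _dump_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def _write_rules_tsv(rules, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("conditions\tpredicted_class\tn_covered\tn_misclassified\n")
        for rule in rules:
            conds = "; ".join(
                f"{c.probe_id} {c.op} {_FLOAT_FMT % c.threshold}"
                for c in rule.conditions
            )
            fh.write(
                f"{conds}\t{rule.predicted_class}\t{rule.n_covered}"
                f"\t{rule.n_misclassified}\n"
            )


def _read_rules_tsv(path: Path):
    from .tree import Condition, Rule

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != [
        "conditions",
        "predicted_class",
        "n_covered",
        "n_misclassified",
    ]:
        raise FormatError(f"{path}: not a rules table")
    rules = []
    for line in lines[1:]:
        if not line.strip():
            continue
        conds_str, cls, n_cov, n_mis = line.split("\t")
        conditions = []
        if conds_str.strip():
            for chunk in conds_str.split(";"):
                m = _COND_RE.match(chunk.strip())
                if not m:
                    raise ParseError(f"{path}: bad condition {chunk!r}")
                conditions.append(
                    Condition(m["probe"], m["op"], float(m["thr"]))
                )
        rules.append(Rule(conditions, cls, int(n_cov), int(n_mis)))
    return rules
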