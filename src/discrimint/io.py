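"""Readers and writers: CSV data matrices, JSON pattern lists, rule reports.

Matrix CSV: header row mandatory; the outcome column is designated by name
and auto-typed (numerical iff every value parses as a finite number, with an
explicit override).  Predictor cells are kept as category strings; empty
cells are missing and never match a pattern.

Pattern JSON: an array of objects ``{"label": str, "columns": {col: category},
"rows": [row_id, ...]}`` with at least one of ``columns``/``rows`` present.

Reports are written as flat CSV (one row per pattern x consequent, metric
values at 6 significant digits, infinite bounds as "-inf"/"inf") or as fully
nested JSON.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .core import DataError, DataMatrix, Pattern
from .metrics import METRIC_REGISTRY, MetricReport, REFERENCE_THRESHOLDS

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_patterns",
    "write_report",
    "report_to_dict",
    "reports_to_frame",
]


@dataclass
class RunConfig:
    """One assessment run, as configured from the command line."""

    data: Path
    outcome_col: str
    patterns: Path
    setup: str = "empirical"
    outcome_kind: Optional[str] = None
    theta: float = 1.3
    mode: str = "all"
    strict: bool = False
    output: Optional[Path] = None
    fmt: str = "csv"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise DataError("lift threshold must be positive")


def read_matrix(
    path: Union[str, Path],
    outcome_col: str,
    kind: Optional[str] = None,
) -> DataMatrix:
    """Load a CSV data matrix and split off the designated outcome column."""
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise DataError(f"data file not found: {path}")
    except pd.errors.EmptyDataError:
        raise DataError(f"data file is empty: {path}")
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed CSV {path}: {exc}")
    if frame.empty:
        raise DataError(f"data file has a header but no rows: {path}")
    return DataMatrix.from_frame(frame, outcome_col, kind=kind)


def read_patterns(path: Union[str, Path]) -> List[Pattern]:
    """Load and validate a JSON pattern list, preserving order.

    Category values are normalised to strings so they compare against CSV
    predictor cells; row entries are row identifiers matched against the
    matrix index at coverage time.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except FileNotFoundError:
        raise DataError(f"pattern file not found: {path}")
    except json.JSONDecodeError as exc:
        raise DataError(f"invalid JSON in {path}: {exc}")
    if not isinstance(payload, list):
        raise DataError(f"{path}: expected a JSON array of pattern objects")
    patterns: List[Pattern] = []
    for i, item in enumerate(payload):
        if not isinstance(item, dict):
            raise DataError(f"{path}: pattern #{i} is not an object")
        columns = item.get("columns")
        rows = item.get("rows")
        label = item.get("label", f"pattern_{i}")
        if columns is None and rows is None:
            raise DataError(
                f"{path}: pattern #{i} needs 'columns' and/or 'rows'"
            )
        if columns is not None:
            if not isinstance(columns, dict):
                raise DataError(f"{path}: pattern #{i}: 'columns' must be an object")
            columns = {str(k): str(v) for k, v in columns.items()}
        if rows is not None and not isinstance(rows, list):
            raise DataError(f"{path}: pattern #{i}: 'rows' must be an array")
        patterns.append(
            Pattern.from_mapping(columns=columns, rows=rows, label=str(label))
        )
    return patterns


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return "undefined"
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return f"{value:.6g}"


_COUNT_COLS = ("n_total", "n_antecedent", "n_consequent", "n_joint")


def _report_rows(reports: Sequence[MetricReport]) -> List[Dict[str, str]]:
    rows = []
    for rep in reports:
        for ra in rep.rules:
            row: Dict[str, str] = {
                "pattern": rep.pattern.label,
                "setup": rep.setup,
                "outcome_kind": rep.outcome_kind,
                "consequent": ra.consequent_text,
                "is_best_class": (
                    str(ra.consequent_text == rep.best_class).lower()
                    if rep.best_class is not None
                    else ""
                ),
            }
            for col, v in zip(_COUNT_COLS, ra.counts.as_tuple()):
                row[col] = str(v)
            names = list(METRIC_REGISTRY) + ["Statistical Significance"]
            for name in names:
                row[name] = _fmt(ra.metrics.get(name))
            for name in REFERENCE_THRESHOLDS:
                flag = ra.flags.get(name)
                row[f"flag:{name}"] = "" if flag is None else str(flag).lower()
            rows.append(row)
    return rows


def _columns() -> List[str]:
    return (
        ["pattern", "setup", "outcome_kind", "consequent", "is_best_class"]
        + list(_COUNT_COLS)
        + list(METRIC_REGISTRY)
        + ["Statistical Significance"]
        + [f"flag:{name}" for name in REFERENCE_THRESHOLDS]
    )


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Flat one-row-per-rule DataFrame with the deterministic column order."""
    return pd.DataFrame(_report_rows(reports), columns=_columns())


def report_to_dict(report: MetricReport) -> Dict:
    """JSON-ready nested representation of one report."""
    return {
        "pattern": {
            "label": report.pattern.label,
            "columns": {c: v for c, v in report.pattern.descriptor},
            "rows": sorted(report.pattern.rows, key=str)
            if report.pattern.rows is not None
            else None,
        },
        "setup": report.setup,
        "outcome_kind": report.outcome_kind,
        "best_class": report.best_class,
        "warnings": list(report.warnings),
        "rules": [
            {
                "consequent": ra.consequent_text,
                "counts": dict(zip(_COUNT_COLS, ra.counts.as_tuple())),
                "metrics": {
                    k: (None if v is None else v) for k, v in ra.metrics.items()
                },
                "undefined": dict(ra.undefined),
                "flags": dict(ra.flags),
            }
            for ra in report.rules
        ],
    }


def write_report(
    reports: Sequence[MetricReport],
    path: Union[str, Path],
    fmt: str = "csv",
) -> None:
    """Write reports as CSV (flat) or JSON (nested); deterministic output."""
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            writer = csv.DictWriter(fh, fieldnames=_columns())
            writer.writeheader()
            for row in _report_rows(reports):
                writer.writerow(row)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump([report_to_dict(r) for r in reports], fh, indent=2)
            fh.write("\n")
    else:
        raise DataError(f"unknown report format {fmt!r} (csv or json)")
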