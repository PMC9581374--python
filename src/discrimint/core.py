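"""Core data model: data matrices, patterns, coverage and contingency counts.

Everything downstream (interval inference, interestingness metrics) consumes
the four coverage counts of an association rule ``pattern -> consequent``::

    N  = number of observations
    f  = coverage of the antecedent pattern
    g  = coverage of the consequent (class label or interval union)
    a  = joint coverage (rows where both hold)

collected here as :class:`ContingencyCounts`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

NUMERICAL = "numerical"
CATEGORICAL = "categorical"


class DataError(ValueError):
    """Invalid or inconsistent input data."""


class UsageError(ValueError):
    """API misuse: mismatched kinds, empty inputs, unknown options."""


class DegenerateInputError(DataError):
    """Input too degenerate for the requested operation (e.g. empty coverage)."""


@dataclass(frozen=True)
class OutcomeVector:
    """Designated outcome column of a data matrix.

    Parameters
    ----------
    kind : {"numerical", "categorical"}
    values : ndarray
        Per-observation outcome: finite floats (numerical) or labels
        (categorical).
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (NUMERICAL, CATEGORICAL):
            raise UsageError(f"unknown outcome kind: {self.kind!r}")
        if self.kind == NUMERICAL:
            arr = np.asarray(self.values, dtype=float)
            if arr.ndim != 1:
                raise DataError("outcome must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise DataError("numerical outcome contains non-finite values")
        else:
            arr = np.asarray(self.values, dtype=object)
            if arr.ndim != 1:
                raise DataError("outcome must be one-dimensional")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def labels(self) -> Tuple:
        """Sorted distinct labels (categorical outcomes only)."""
        if self.kind != CATEGORICAL:
            raise UsageError("labels are defined for categorical outcomes only")
        return tuple(sorted(set(self.values), key=str))


@dataclass
class DataMatrix:
    """Observations x predictors table plus a designated outcome vector.

    ``predictors`` is a :class:`pandas.DataFrame` whose index supplies the
    observation identifiers (``row_ids``); the outcome column has already been
    split off into ``outcome``.
    """

    predictors: pd.DataFrame
    outcome: OutcomeVector

    def __post_init__(self) -> None:
        if self.predictors.index.has_duplicates:
            raise DataError("row identifiers must be unique")
        if self.predictors.columns.has_duplicates:
            raise DataError("column names must be unique")
        if len(self.predictors) != len(self.outcome):
            raise DataError(
                f"outcome length {len(self.outcome)} does not match "
                f"{len(self.predictors)} rows"
            )
        if len(self.predictors) == 0:
            raise DataError("data matrix has no observations")

    @property
    def n_rows(self) -> int:
        return len(self.predictors)

    @property
    def row_ids(self) -> Tuple:
        return tuple(self.predictors.index)

    @property
    def col_ids(self) -> Tuple[str, ...]:
        return tuple(self.predictors.columns)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome_col: str,
        kind: Optional[str] = None,
    ) -> "DataMatrix":
        """Split ``outcome_col`` off ``frame`` and build a typed matrix.

        The outcome is auto-detected as numerical iff every value parses as a
        finite number; ``kind`` overrides the detection.
        """
        if outcome_col not in frame.columns:
            raise DataError(
                f"outcome column {outcome_col!r} not found; available: "
                f"{list(frame.columns)}"
            )
        raw = frame[outcome_col]
        if raw.isna().any():
            raise DataError(f"outcome column {outcome_col!r} has missing values")
        numeric = pd.to_numeric(raw, errors="coerce")
        is_numeric = bool(numeric.notna().all()) and bool(
            np.isfinite(numeric.to_numpy(dtype=float)).all()
        )
        if kind is None:
            kind = NUMERICAL if is_numeric else CATEGORICAL
        if kind == NUMERICAL:
            if not is_numeric:
                raise DataError(
                    f"outcome column {outcome_col!r} cannot be parsed as numerical"
                )
            outcome = OutcomeVector(NUMERICAL, numeric.to_numpy(dtype=float))
        else:
            outcome = OutcomeVector(
                CATEGORICAL, raw.astype(str).to_numpy(dtype=object)
            )
        return cls(frame.drop(columns=[outcome_col]), outcome)


@dataclass(frozen=True)
class Pattern:
    """Rule antecedent: column->category pairs and/or explicit covered rows.

    ``descriptor`` lists the expected value per column (the pattern of a
    constant-on-columns subspace); ``rows`` optionally gives the covered row
    identifiers directly.  At least one of the two must be present; when both
    are, they must agree (validated at coverage time).
    """

    descriptor: Tuple[Tuple[str, object], ...] = ()
    rows: Optional[frozenset] = None
    label: str = ""

    def __post_init__(self) -> None:
        desc = tuple((str(c), v) for c, v in self.descriptor)
        object.__setattr__(self, "descriptor", desc)
        if self.rows is not None:
            object.__setattr__(self, "rows", frozenset(self.rows))
        if not desc and self.rows is None:
            raise UsageError(
                f"pattern {self.label!r}: needs a descriptor or explicit rows"
            )

    @classmethod
    def from_mapping(
        cls,
        columns: Optional[Mapping[str, object]] = None,
        rows: Optional[Iterable] = None,
        label: str = "",
    ) -> "Pattern":
        desc = tuple(columns.items()) if columns else ()
        return cls(desc, frozenset(rows) if rows is not None else None, label)


def coverage_mask(matrix: DataMatrix, pattern: Pattern) -> np.ndarray:
    """Boolean per-row mask of the pattern's coverage.

    A row is covered iff every (column, category) pair of the descriptor
    matches its cell exactly; missing cells never match.  Explicit rows are
    translated from row identifiers to positions.  When both encodings are
    given they must agree, otherwise a :class:`DataError` is raised.
    """
    n = matrix.n_rows
    desc_mask: Optional[np.ndarray] = None
    if pattern.descriptor:
        desc_mask = np.ones(n, dtype=bool)
        for col, cat in pattern.descriptor:
            if col not in matrix.predictors.columns:
                raise DataError(
                    f"pattern {pattern.label!r}: unknown column {col!r}; "
                    f"available: {list(matrix.predictors.columns)}"
                )
            series = matrix.predictors[col]
            desc_mask &= (series == cat).to_numpy(dtype=bool) & series.notna().to_numpy()

    rows_mask: Optional[np.ndarray] = None
    if pattern.rows is not None:
        rows_mask = np.zeros(n, dtype=bool)
        indexer = matrix.predictors.index.get_indexer(list(pattern.rows))
        if (indexer < 0).any():
            missing = [r for r, i in zip(pattern.rows, indexer) if i < 0]
            raise DataError(
                f"pattern {pattern.label!r}: unknown row identifiers {missing!r}"
            )
        rows_mask[indexer] = True

    if desc_mask is not None and rows_mask is not None:
        if not np.array_equal(desc_mask, rows_mask):
            raise DataError(
                f"pattern {pattern.label!r}: descriptor coverage disagrees "
                "with the explicit row list"
            )
    mask = desc_mask if desc_mask is not None else rows_mask
    assert mask is not None
    return mask


def compute_coverage(matrix: DataMatrix, pattern: Pattern) -> set:
    """Covered row positions (0-based) as a set; may be empty."""
    return set(np.flatnonzero(coverage_mask(matrix, pattern)).tolist())


@dataclass(frozen=True)
class ContingencyCounts:
    """The four coverage counts of a rule: (N, f, g, a)."""

    n_total: int
    n_antecedent: int
    n_consequent: int
    n_joint: int

    def __post_init__(self) -> None:
        n, f, g, a = (
            self.n_total,
            self.n_antecedent,
            self.n_consequent,
            self.n_joint,
        )
        if n <= 0:
            raise DataError("n_total must be positive")
        if not (0 <= a <= min(f, g)):
            raise DataError(f"n_joint {a} outside [0, min({f}, {g})]")
        if f > n or g > n or f < 0 or g < 0:
            raise DataError("antecedent/consequent counts outside [0, N]")

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.n_total, self.n_antecedent, self.n_consequent, self.n_joint)


def contingency_from_masks(
    antecedent: np.ndarray, consequent: np.ndarray
) -> ContingencyCounts:
    antecedent = np.asarray(antecedent, dtype=bool)
    consequent = np.asarray(consequent, dtype=bool)
    return ContingencyCounts(
        n_total=int(antecedent.size),
        n_antecedent=int(antecedent.sum()),
        n_consequent=int(consequent.sum()),
        n_joint=int((antecedent & consequent).sum()),
    )


def build_contingency(
    matrix: DataMatrix,
    pattern: Pattern,
    consequent: Union["IntervalSetLike", object],
) -> ContingencyCounts:
    """Count (N, f, g, a) for ``pattern -> consequent``.

    ``consequent`` is an interval set (numerical outcome; membership with
    closed bounds at both ends) or a class label (categorical outcome).
    """
    ante = coverage_mask(matrix, pattern)
    if matrix.outcome.kind == NUMERICAL:
        if not hasattr(consequent, "contains"):
            raise UsageError(
                "numerical outcome requires an interval-set consequent, "
                f"got {type(consequent).__name__}"
            )
        member = consequent.contains(matrix.outcome.values)
    else:
        if hasattr(consequent, "contains"):
            raise UsageError(
                "categorical outcome requires a class-label consequent"
            )
        member = matrix.outcome.values == consequent
    return contingency_from_masks(ante, member)


class IntervalSetLike:  # pragma: no cover - typing aid only
    def contains(self, x):
        raise NotImplementedError
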