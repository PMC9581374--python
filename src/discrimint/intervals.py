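"""Consequent-interval inference, pruning and selection.

Turns a pattern's conditional outcomes into a discriminative consequent under
one of four setups:

``min_max``
    [min, max] of the pattern-conditional outcomes.
``average``
    [mu - sigma, mu + sigma] of the pattern-conditional outcomes
    (population standard deviation).
``gaussian``
    Analytic intersection of Gaussian fits to the overall and conditional
    outcomes.
``empirical``
    Linear-time intersection of the two relative-frequency pdfs; this is the
    only setup that can produce multiple intervals, which are then optionally
    pruned by combined lift.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Callable, List, Sequence

import numpy as np

from .core import (
    NUMERICAL,
    ContingencyCounts,
    DataMatrix,
    DegenerateInputError,
    OutcomeVector,
    Pattern,
    UsageError,
    build_contingency,
    coverage_mask,
)
from .distributions import (
    IntervalSet,
    empirical_intersection,
    empirical_pdf,
    gaussian_fit,
    gaussian_intersection,
)

__all__ = [
    "SETUPS",
    "IntervalSet",
    "infer_intervals",
    "prune_intervals",
    "candidate_consequents",
    "select_consequent",
    "discretize_outcome",
]

SETUPS = ("empirical", "gaussian", "min_max", "average")

ContingencyBuilder = Callable[[IntervalSet], ContingencyCounts]


def _lift(counts: ContingencyCounts) -> float:
    n, f, g, a = counts.as_tuple()
    if f == 0 or g == 0:
        return float("-inf")
    return a * n / (f * g)


def infer_intervals(
    matrix: DataMatrix,
    pattern: Pattern,
    setup: str,
    strict: bool = False,
) -> IntervalSet:
    """Infer the discriminative outcome interval(s) for ``pattern``.

    Requires a numerical outcome and nonempty pattern coverage.  The gaussian
    setup falls back to min_max (with ``fallback=True`` and a warning) when
    either fitted standard deviation is zero.
    """
    if setup not in SETUPS:
        raise UsageError(f"unknown setup {setup!r}; choose one of {SETUPS}")
    if matrix.outcome.kind != NUMERICAL:
        raise UsageError("interval inference requires a numerical outcome")
    mask = coverage_mask(matrix, pattern)
    if not mask.any():
        raise DegenerateInputError(
            f"pattern {pattern.label!r} covers no observations"
        )
    overall = matrix.outcome.values
    conditional = overall[mask]

    if setup == "min_max":
        return IntervalSet(
            ((float(conditional.min()), float(conditional.max())),),
            setup="min_max",
        )
    if setup == "average":
        mu = float(conditional.mean())
        sigma = float(conditional.std(ddof=0))
        return IntervalSet(((mu - sigma, mu + sigma),), setup="average")
    if setup == "gaussian":
        fit_all = gaussian_fit(overall)
        fit_cond = gaussian_fit(conditional)
        if fit_all.degenerate or fit_cond.degenerate:
            warnings.warn(
                f"pattern {pattern.label!r}: degenerate gaussian fit, "
                "falling back to min_max bounds",
                stacklevel=2,
            )
            return IntervalSet(
                ((float(conditional.min()), float(conditional.max())),),
                setup="gaussian",
                fallback=True,
            )
        return gaussian_intersection(fit_all, fit_cond)
    support = np.unique(overall)
    pdf_all = empirical_pdf(overall, support)
    pdf_cond = empirical_pdf(conditional, support)
    return empirical_intersection(pdf_all, pdf_cond, strict=strict)


def prune_intervals(
    interval_set: IntervalSet,
    contingency_builder: ContingencyBuilder,
    theta: float = 1.3,
) -> IntervalSet:
    """Iteratively drop low-lift intervals until the union's lift passes theta.

    If the combined lift of the full union already reaches ``theta`` the set
    is returned unchanged.  Otherwise the interval with the lowest individual
    lift (ties: the one with smaller consequent coverage) is dropped and the
    combined lift recomputed, until it passes or every interval would be
    removed -- in which case the original full set is returned, flagged
    non-discriminative.
    """
    current = interval_set
    while True:
        combined = _lift(contingency_builder(current))
        if combined >= theta:
            return current
        if len(current) <= 1:
            return replace(interval_set, discriminative=False)
        scored = []
        for k, single in enumerate(current.singles()):
            counts = contingency_builder(single)
            scored.append((_lift(counts), counts.n_consequent, k))
        _, _, worst = min(scored)
        kept = tuple(iv for k, iv in enumerate(current.intervals) if k != worst)
        current = replace(current, intervals=kept)


def candidate_consequents(interval_set: IntervalSet) -> List[IntervalSet]:
    """The selection candidates: the full union plus each single interval."""
    if len(interval_set) == 1:
        return [interval_set]
    return [interval_set] + interval_set.singles()


def select_consequent(
    candidates: Sequence[IntervalSet],
    contingency_builder: ContingencyBuilder,
    mode: str,
    theta: float = 1.3,
) -> List[IntervalSet]:
    """Pick consequent(s) among candidate interval unions by lift.

    ``argmax`` returns the single candidate maximising lift; ``threshold``
    returns every candidate whose lift reaches ``theta`` (possibly none).
    """
    if not candidates:
        raise UsageError("select_consequent needs at least one candidate")
    if mode not in ("argmax", "threshold"):
        raise UsageError(f"unknown selection mode {mode!r}")
    lifts = [_lift(contingency_builder(c)) for c in candidates]
    if mode == "argmax":
        return [candidates[int(np.argmax(lifts))]]
    return [c for c, l in zip(candidates, lifts) if l >= theta]


def discretize_outcome(
    outcome: OutcomeVector, interval_set: IntervalSet
) -> np.ndarray:
    """Binary in-consequent vector: closed-bound membership in the union."""
    if outcome.kind != NUMERICAL:
        raise UsageError("discretize_outcome requires a numerical outcome")
    return interval_set.contains(outcome.values)


def interval_contingency(
    matrix: DataMatrix, pattern: Pattern, interval_set: IntervalSet
) -> ContingencyCounts:
    """Convenience contingency builder bound to a matrix and pattern."""
    return build_contingency(matrix, pattern, interval_set)
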