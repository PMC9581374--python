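"""Interestingness-measure formulary and the batch assessment driver.

Every metric consumes the contingency counts ``(N, f, g, a)`` of a rule
``pattern -> consequent`` (antecedent coverage f, consequent coverage g,
joint coverage a) except statistical significance, which scores the pattern
itself against column-marginal expectations.  With ``P(A) = f/N``,
``P(C) = g/N``, ``P(AC) = a/N``:

================================  ==============================================
Rule Support                      a / N
Coverage (Support)                f / N
Confidence                        a / f
Lift                              a * N / (f * g)
Standardised Lift                 (lift - lmb) / (ups - lmb), with
                                  lmb = max(P(A)+P(C)-1, 1/N) / (P(A) P(C)),
                                  ups = 1 / max(P(A), P(C))
Information Gain                  H(C) - [P(A) H(C|A) + P(!A) H(C|!A)], base 2
Gini Index                        gini(C) - [P(A) gini(C|A) + P(!A) gini(C|!A)]
Chi-Squared                       Pearson statistic of the 2x2 table, 1 df,
                                  no continuity correction
Statistical Significance          one-sided binomial tail P(X >= f) with
                                  X ~ Binomial(N, p_phi), p_phi the product of
                                  the column-marginal category frequencies of
                                  the pattern descriptor
All-Confidence                    a / max(f, g)
Laplace Corrected Confidence      (a + 1) / (f + 2)
Descriptive Confirmed Confidence  2 a/f - 1
Casual Confidence                 (a/f + (N-f-g+a)/(N-g)) / 2
Casual Support                    (a + N-f-g+a) / N
Difference in Support             a/g - (f-a)/(N-g)
Bigger Support                    max(a/g, (f-a)/(N-g))
Hyper Confidence                  P(X <= a), X ~ Hypergeom(N, g, f)
Hyper Lift                        a / Q_{0.99}(X), same hypergeometric
================================  ==============================================

Metrics whose denominators vanish are reported as explicit *undefined*
markers, never as zero or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .core import (
    CATEGORICAL,
    NUMERICAL,
    ContingencyCounts,
    DataMatrix,
    DegenerateInputError,
    Pattern,
    UsageError,
    build_contingency,
    coverage_mask,
)
from .distributions import IntervalSet
from .intervals import (
    candidate_consequents,
    infer_intervals,
    prune_intervals,
    select_consequent,
)

__all__ = [
    "UndefinedMetric",
    "METRIC_REGISTRY",
    "UNIMPLEMENTED_METRICS",
    "REFERENCE_THRESHOLDS",
    "RuleAssessment",
    "MetricReport",
    "confidence",
    "lift",
    "standardised_lift",
    "chi_squared",
    "information_gain",
    "gini_index",
    "statistical_significance",
    "evaluate_counts",
    "threshold_flags",
    "best_class_by_lift",
    "assess",
]


class UndefinedMetric(ArithmeticError):
    """A metric is undefined for these counts (vanishing denominator etc.)."""


def _unpack(counts: ContingencyCounts) -> Tuple[int, int, int, int]:
    return counts.as_tuple()


# ---------------------------------------------------------------- basic family


def rule_support(counts: ContingencyCounts) -> float:
    n, _, _, a = _unpack(counts)
    return a / n


def antecedent_support(counts: ContingencyCounts) -> float:
    n, f, _, _ = _unpack(counts)
    return f / n


def confidence(counts: ContingencyCounts) -> float:
    _, f, _, a = _unpack(counts)
    if f == 0:
        raise UndefinedMetric("confidence: empty antecedent coverage")
    return a / f


def lift(counts: ContingencyCounts) -> float:
    n, f, g, a = _unpack(counts)
    if f == 0 or g == 0:
        raise UndefinedMetric("lift: empty antecedent or consequent coverage")
    return a * n / (f * g)


def standardised_lift(counts: ContingencyCounts) -> float:
    """Lift rescaled to [0, 1] by its margin-constrained attainable range."""
    n, f, g, a = _unpack(counts)
    if f == 0 or g == 0:
        raise UndefinedMetric("standardised lift: empty margin")
    p_a, p_c = f / n, g / n
    # lmb and ups are the lifts at joint counts max(f+g-N, 1) and min(f, g);
    # the integer comparison avoids float ties when the range collapses
    if max(f + g - n, 1) == min(f, g):
        raise UndefinedMetric("standardised lift: margins admit a single value")
    lmb = max(p_a + p_c - 1.0, 1.0 / n) / (p_a * p_c)
    ups = 1.0 / max(p_a, p_c)
    if ups <= lmb:
        raise UndefinedMetric("standardised lift: margins admit a single value")
    value = (lift(counts) - lmb) / (ups - lmb)
    return min(1.0, max(0.0, value))


def chi_squared(counts: ContingencyCounts) -> float:
    """Pearson chi-squared of the 2x2 table, 1 df, no continuity correction."""
    n, f, g, a = _unpack(counts)
    if f == 0 or g == 0 or f == n or g == n:
        raise UndefinedMetric("chi-squared: zero expected cell")
    det = a * (n - f - g + a) - (f - a) * (g - a)
    return n * det * det / (f * g * (n - f) * (n - g))


def _entropy2(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def _gini2(p: float) -> float:
    return 1.0 - p * p - (1 - p) * (1 - p)


def _split_gain(counts: ContingencyCounts, impurity: Callable[[float], float]) -> float:
    n, f, g, a = _unpack(counts)
    prior = impurity(g / n)
    if f == 0 or f == n:
        return 0.0
    cond = (f / n) * impurity(a / f) + ((n - f) / n) * impurity((g - a) / (n - f))
    return max(0.0, prior - cond)


def information_gain(counts: ContingencyCounts) -> float:
    """Base-2 entropy reduction of the consequent split by the antecedent."""
    return _split_gain(counts, _entropy2)


def gini_index(counts: ContingencyCounts) -> float:
    """Gini-impurity reduction of the consequent split by the antecedent."""
    return _split_gain(counts, _gini2)


# ------------------------------------------------------------ extended family


def all_confidence(counts: ContingencyCounts) -> float:
    _, f, g, a = _unpack(counts)
    if max(f, g) == 0:
        raise UndefinedMetric("all-confidence: empty margins")
    return a / max(f, g)


def laplace_confidence(counts: ContingencyCounts) -> float:
    _, f, _, a = _unpack(counts)
    return (a + 1) / (f + 2)


def descriptive_confirmed_confidence(counts: ContingencyCounts) -> float:
    _, f, _, a = _unpack(counts)
    if f == 0:
        raise UndefinedMetric("descriptive confirmed confidence: empty antecedent")
    return 2 * a / f - 1


def casual_confidence(counts: ContingencyCounts) -> float:
    n, f, g, a = _unpack(counts)
    if f == 0 or n == g:
        raise UndefinedMetric("casual confidence: vanishing denominator")
    return 0.5 * (a / f + (n - f - g + a) / (n - g))


def casual_support(counts: ContingencyCounts) -> float:
    n, f, g, a = _unpack(counts)
    return (a + n - f - g + a) / n


def difference_in_support(counts: ContingencyCounts) -> float:
    n, f, g, a = _unpack(counts)
    if g == 0 or g == n:
        raise UndefinedMetric("difference in support: vanishing denominator")
    return a / g - (f - a) / (n - g)


def bigger_support(counts: ContingencyCounts) -> float:
    n, f, g, a = _unpack(counts)
    if g == 0 or g == n:
        raise UndefinedMetric("bigger support: vanishing denominator")
    return max(a / g, (f - a) / (n - g))


def hyper_confidence(counts: ContingencyCounts) -> float:
    """Cumulative hypergeometric P(X <= a) under fixed rule margins."""
    n, f, g, a = _unpack(counts)
    return float(stats.hypergeom.cdf(a, n, g, f))


def hyper_lift(counts: ContingencyCounts) -> float:
    """Joint coverage relative to the 0.99 hypergeometric quantile."""
    n, f, g, a = _unpack(counts)
    q99 = float(stats.hypergeom.ppf(0.99, n, g, f))
    if q99 <= 0:
        raise UndefinedMetric("hyper lift: zero 0.99 quantile")
    return a / q99


def statistical_significance(
    matrix: DataMatrix, pattern: Pattern, counts: ContingencyCounts
) -> float:
    """Binomial tail probability of the pattern's coverage under independence.

    The null expects each descriptor column to show its category at the
    column-marginal rate independently, so the pattern occurs per row with
    probability ``p_phi``, the product of those marginal frequencies.  The
    p-value is ``P(X >= f)`` for ``X ~ Binomial(N, p_phi)``.  Patterns given
    only as explicit rows have no expectation model and are undefined.
    """
    if not pattern.descriptor:
        raise UndefinedMetric(
            "statistical significance: pattern has no column descriptor"
        )
    n, f, _, _ = _unpack(counts)
    p_phi = 1.0
    for col, cat in pattern.descriptor:
        series = matrix.predictors[col]
        p_phi *= float((series == cat).sum()) / n
    return float(stats.binom.sf(f - 1, n, p_phi))


METRIC_REGISTRY: Dict[str, Callable[[ContingencyCounts], float]] = {
    "Rule Support": rule_support,
    "Coverage (Support)": antecedent_support,
    "Confidence": confidence,
    "Lift": lift,
    "Standardised Lift": standardised_lift,
    "Information Gain": information_gain,
    "Gini Index": gini_index,
    "Chi-Squared": chi_squared,
    "All-Confidence": all_confidence,
    "Laplace Corrected Confidence": laplace_confidence,
    "Descriptive Confirmed Confidence": descriptive_confirmed_confidence,
    "Casual Confidence": casual_confidence,
    "Casual Support": casual_support,
    "Difference in Support": difference_in_support,
    "Bigger Support": bigger_support,
    "Hyper Confidence": hyper_confidence,
    "Hyper Lift": hyper_lift,
}

#: Named in the metric taxonomy but defined only in an external source whose
#: weighting scheme is not reproduced here; listed so callers can see the gap.
UNIMPLEMENTED_METRICS: Tuple[str, ...] = (
    "Weighted Support",
    "Weighted Rule Support",
    "Weighted Confidence",
    "Weighted Lift",
)

#: Reference decision thresholds per metric: (comparison, cutoff).
REFERENCE_THRESHOLDS: Dict[str, Tuple[str, float]] = {
    "Information Gain": (">", 0.6),
    "Gini Index": (">", 0.6),
    "Chi-Squared": (">", 3.84),
    "Lift": (">", 1.3),
    "Standardised Lift": (">", 0.6),
    "Statistical Significance": ("<", 0.05),
}


def evaluate_counts(
    counts: ContingencyCounts,
    matrix: Optional[DataMatrix] = None,
    pattern: Optional[Pattern] = None,
) -> Tuple[Dict[str, Optional[float]], Dict[str, str]]:
    """All registry metrics for one rule; undefined ones become markers.

    Returns ``(values, undefined)`` where undefined metrics appear as ``None``
    in ``values`` and carry their reason in ``undefined``.
    """
    values: Dict[str, Optional[float]] = {}
    undefined: Dict[str, str] = {}
    for name, fn in METRIC_REGISTRY.items():
        try:
            values[name] = float(fn(counts))
        except UndefinedMetric as exc:
            values[name] = None
            undefined[name] = str(exc)
    if matrix is not None and pattern is not None:
        try:
            values["Statistical Significance"] = statistical_significance(
                matrix, pattern, counts
            )
        except UndefinedMetric as exc:
            values["Statistical Significance"] = None
            undefined["Statistical Significance"] = str(exc)
    return values, undefined


def threshold_flags(values: Dict[str, Optional[float]]) -> Dict[str, Optional[bool]]:
    """Reference-threshold pass/fail flags; None where the metric is undefined."""
    flags: Dict[str, Optional[bool]] = {}
    for name, (op, cutoff) in REFERENCE_THRESHOLDS.items():
        v = values.get(name)
        if v is None:
            flags[name] = None
        elif op == ">":
            flags[name] = v > cutoff
        else:
            flags[name] = v < cutoff
    return flags


@dataclass
class RuleAssessment:
    """One rule ``pattern -> consequent`` with its counts, metrics and flags."""

    consequent: Union[IntervalSet, str]
    counts: ContingencyCounts
    metrics: Dict[str, Optional[float]]
    undefined: Dict[str, str]
    flags: Dict[str, Optional[bool]]

    @property
    def consequent_text(self) -> str:
        if isinstance(self.consequent, IntervalSet):
            return self.consequent.format()
        return str(self.consequent)


@dataclass
class MetricReport:
    """Assessment of one pattern: one or more scored rules plus metadata."""

    pattern: Pattern
    setup: str
    outcome_kind: str
    rules: List[RuleAssessment] = field(default_factory=list)
    best_class: Optional[str] = None
    warnings: List[str] = field(default_factory=list)


def _assess_consequent(
    matrix: DataMatrix, pattern: Pattern, consequent: Union[IntervalSet, str]
) -> RuleAssessment:
    counts = build_contingency(matrix, pattern, consequent)
    values, undefined = evaluate_counts(counts, matrix, pattern)
    return RuleAssessment(
        consequent=consequent,
        counts=counts,
        metrics=values,
        undefined=undefined,
        flags=threshold_flags(values),
    )


def best_class_by_lift(
    matrix: DataMatrix, pattern: Pattern
) -> Tuple[str, RuleAssessment]:
    """The outcome class maximising lift for this pattern.

    Ties are broken by higher rule support, then lexicographic label.
    Requires a categorical outcome with at least two classes.
    """
    if matrix.outcome.kind != CATEGORICAL:
        raise UsageError("best_class_by_lift requires a categorical outcome")
    labels = matrix.outcome.labels
    if len(labels) < 2:
        raise UsageError("best_class_by_lift needs at least two outcome classes")
    best: Optional[Tuple[float, float, str, RuleAssessment]] = None
    for label in labels:
        ra = _assess_consequent(matrix, pattern, label)
        lift_v = ra.metrics.get("Lift")
        if lift_v is None:
            continue
        supp = ra.metrics["Rule Support"] or 0.0
        key = (-lift_v, -supp, str(label))
        if best is None or key < (best[0], best[1], best[2]):
            best = (key[0], key[1], key[2], ra)
    if best is None:
        raise UsageError("lift undefined for every outcome class")
    return best[2], best[3]


def assess(
    matrix: DataMatrix,
    patterns: Sequence[Pattern],
    setup: str = "empirical",
    theta: float = 1.3,
    mode: str = "all",
    strict: bool = False,
) -> List[MetricReport]:
    """Score every pattern against its inferred (or class) consequent.

    Numerical outcomes: infer intervals per ``setup``, prune multi-interval
    empirical consequents by combined lift against ``theta``, then score the
    binarised consequent.  ``mode`` controls which consequent(s) are scored:
    ``all`` keeps the (pruned) union, ``argmax``/``threshold`` apply the
    lift-based selection over the union and its single intervals.

    Categorical outcomes: one scored rule per class, with the best class by
    lift recorded on the report.

    Per-metric failures are reported as undefined markers; per-pattern
    degeneracies (empty coverage) produce a report with a warning instead of
    aborting the batch.
    """
    reports: List[MetricReport] = []
    for pattern in patterns:
        report = MetricReport(
            pattern=pattern, setup=setup, outcome_kind=matrix.outcome.kind
        )
        if matrix.outcome.kind == CATEGORICAL:
            for label in matrix.outcome.labels:
                report.rules.append(_assess_consequent(matrix, pattern, label))
            try:
                report.best_class = best_class_by_lift(matrix, pattern)[0]
            except UsageError as exc:
                report.warnings.append(str(exc))
            reports.append(report)
            continue

        try:
            interval_set = infer_intervals(matrix, pattern, setup, strict=strict)
        except DegenerateInputError as exc:
            report.warnings.append(str(exc))
            reports.append(report)
            continue
        if interval_set.fallback:
            report.warnings.append("degenerate gaussian fit: min_max fallback")

        builder = lambda s: build_contingency(matrix, pattern, s)  # noqa: E731
        if setup == "empirical" and len(interval_set) > 1:
            interval_set = prune_intervals(interval_set, builder, theta)

        if mode == "all":
            chosen = [interval_set]
        elif mode in ("argmax", "threshold"):
            chosen = select_consequent(
                candidate_consequents(interval_set), builder, mode, theta
            )
            if not chosen:
                report.warnings.append(
                    f"no candidate consequent reaches lift >= {theta}"
                )
        else:
            raise UsageError(f"unknown mode {mode!r}")
        for consequent in chosen:
            report.rules.append(_assess_consequent(matrix, pattern, consequent))
        reports.append(report)
    return reports
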