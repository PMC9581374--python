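"""Outcome distributions and their intersection points.

A pattern's discriminative outcome range is where the pattern-conditional
outcome density exceeds the overall outcome density.  Two representations
are supported:

* empirical relative-frequency pdfs on the shared support of the overall
  outcome, intersected in linear time by a sign-change scan; and
* Gaussian fits, intersected analytically (density equality is a quadratic
  in x).

Both intersections return an :class:`IntervalSet`, the rule consequent
``union_i [v1(i), v2(i)]`` with bounds possibly +-infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import DataError, DegenerateInputError

__all__ = [
    "EmpiricalPdf",
    "GaussianPdf",
    "IntervalSet",
    "empirical_pdf",
    "empirical_intersection",
    "intersection_trace",
    "gaussian_fit",
    "gaussian_intersection",
]

_INF = float("inf")


@dataclass(frozen=True)
class IntervalSet:
    """An ordered union of disjoint closed intervals, the rule consequent.

    Bounds may be ``-inf`` (first interval only) or ``+inf`` (last interval
    only).  ``discriminative`` is False when no informative consequent could
    be inferred (identical distributions, or pruning removed everything);
    ``fallback`` marks an interval produced by a degenerate-input fallback.
    """

    intervals: Tuple[Tuple[float, float], ...]
    setup: str = "empirical"
    discriminative: bool = True
    fallback: bool = False

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_hi = -_INF
        for k, (lo, hi) in enumerate(ivs):
            if lo > hi:
                raise DataError(f"interval {k}: lower {lo} > upper {hi}")
            if lo == -_INF and k != 0:
                raise DataError("-inf bound allowed on the first interval only")
            if hi == _INF and k != len(ivs) - 1:
                raise DataError("+inf bound allowed on the last interval only")
            if k > 0 and lo <= prev_hi:
                raise DataError("intervals must be sorted and disjoint")
            prev_hi = hi

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def is_full_range(self) -> bool:
        return self.intervals == ((-_INF, _INF),)

    def contains(self, x) -> np.ndarray:
        """Vectorised closed-bound membership in the interval union."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape, dtype=bool)
        for lo, hi in self.intervals:
            out |= (x >= lo) & (x <= hi)
        return out

    def singles(self) -> List["IntervalSet"]:
        """Each member interval as its own single-interval set."""
        return [replace(self, intervals=(iv,)) for iv in self.intervals]

    def format(self) -> str:
        parts = [f"[{lo!r},{hi!r}]" for lo, hi in self.intervals]
        if len(parts) == 1:
            return parts[0]
        return "[" + ",".join(parts) + "]"


@dataclass(frozen=True)
class EmpiricalPdf:
    """Relative-frequency pdf on the overall outcome support.

    ``support`` holds the sorted unique values of the *overall* outcome;
    pattern-conditional samples are evaluated on this same support, so
    values absent from the sample carry frequency zero.
    """

    support: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        if support.ndim != 1 or freqs.shape != support.shape:
            raise DataError("support and freqs must be 1-d arrays of equal length")
        if np.any(np.diff(support) <= 0):
            raise DataError("support must be strictly increasing")
        if np.any(freqs < 0):
            raise DataError("frequencies must be nonnegative")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "freqs", freqs)


def empirical_pdf(sample: Sequence[float], support: Sequence[float]) -> EmpiricalPdf:
    """Relative frequency of each support value within ``sample``.

    Every sample value must occur in ``support`` (conditional outcomes are a
    subset of the overall outcomes), otherwise a :class:`DataError` is raised.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise DegenerateInputError("empirical pdf of an empty sample")
    support = np.asarray(support, dtype=float)
    idx = np.searchsorted(support, sample)
    bad = (idx >= support.size) | (support[np.minimum(idx, support.size - 1)] != sample)
    if bad.any():
        raise DataError(
            f"sample values {np.unique(sample[bad]).tolist()} not in support"
        )
    counts = np.bincount(idx, minlength=support.size)
    return EmpiricalPdf(support, counts / sample.size)


def intersection_trace(overall: EmpiricalPdf, conditional: EmpiricalPdf) -> Dict[str, np.ndarray]:
    """The five-step linear-time intersection scan, intermediates included.

    Steps: (i) the two relative-frequency arrays are given; (ii) element-wise
    subtraction overall - conditional; (iii) sign extraction (exact zeros
    count as +1, i.e. ties go to the overall pdf); (iv) first differences of
    the sign vector; (v) nonzero difference indices, each mapping to the
    support value at that position.  Sentinels: a conditional pdf starting
    (ending) above the overall pdf opens (closes) the first (last) interval
    at -inf (+inf).
    """
    if not np.array_equal(overall.support, conditional.support):
        raise DataError("pdfs must share the same support")
    support = overall.support
    subtraction = overall.freqs - conditional.freqs
    sign = np.where(subtraction < 0, -1, 1)
    diff = np.diff(sign)
    nonzero = np.flatnonzero(diff)

    lowers: List[float] = []
    uppers: List[float] = []
    if sign[0] == -1:
        lowers.append(-_INF)
    for i in nonzero:
        if diff[i] < 0:
            lowers.append(float(support[i]))
        else:
            uppers.append(float(support[i]))
    if sign[-1] == -1:
        uppers.append(_INF)

    return {
        "support": support,
        "overall": overall.freqs,
        "conditional": conditional.freqs,
        "subtraction": subtraction,
        "sign": sign,
        "diff": diff,
        "nonzero_indices": nonzero,
        "lowers": np.asarray(lowers),
        "uppers": np.asarray(uppers),
    }


def _dominance_runs(sign: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal index runs where the conditional pdf strictly dominates."""
    runs: List[Tuple[int, int]] = []
    start = None
    for k, s in enumerate(sign):
        if s == -1 and start is None:
            start = k
        elif s == 1 and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(sign) - 1))
    return runs


def empirical_intersection(
    overall: EmpiricalPdf,
    conditional: EmpiricalPdf,
    strict: bool = False,
) -> IntervalSet:
    """Intervals where the conditional pdf exceeds the overall pdf.

    The default bound convention is the literal index->value mapping of the
    sign-change scan: each nonzero difference index maps to the support value
    *at that index*, so the lower bound of a run sits one support value
    before the first dominated value.  ``strict=True`` instead returns the
    tight dominance runs (first to last dominated support value).

    Identical pdfs yield the full range ``[-inf, inf]`` flagged
    non-discriminative.
    """
    trace = intersection_trace(overall, conditional)
    if strict:
        support = trace["support"]
        runs = _dominance_runs(trace["sign"])
        intervals = tuple(
            (float(support[s]), float(support[e])) for s, e in runs
        )
    else:
        intervals = tuple(zip(trace["lowers"].tolist(), trace["uppers"].tolist()))
    if not intervals:
        return IntervalSet(((-_INF, _INF),), setup="empirical", discriminative=False)
    return IntervalSet(intervals, setup="empirical")


@dataclass(frozen=True)
class GaussianPdf:
    """Moment-fitted normal approximation of an outcome sample."""

    mu: float
    sigma: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DataError("sigma must be nonnegative")

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0 or self.n == 1

    def logpdf(self, x: float) -> float:
        z = (x - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2 * math.pi)

    def pdf(self, x: float) -> float:
        return math.exp(self.logpdf(x))


def gaussian_fit(sample: Sequence[float]) -> GaussianPdf:
    """Moment estimates (population standard deviation, divide-by-n)."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise DegenerateInputError("gaussian fit of an empty sample")
    return GaussianPdf(
        mu=float(sample.mean()),
        sigma=float(sample.std(ddof=0)),
        n=int(sample.size),
    )


def _polish_root(x: float, p: GaussianPdf, q: GaussianPdf, iters: int = 4) -> float:
    """Newton steps on log p - log q to push the root to machine precision."""
    for _ in range(iters):
        h = p.logpdf(x) - q.logpdf(x)
        dh = -(x - p.mu) / (p.sigma**2) + (x - q.mu) / (q.sigma**2)
        if dh == 0.0:
            break
        x -= h / dh
    return x


def gaussian_intersection(overall: GaussianPdf, conditional: GaussianPdf) -> IntervalSet:
    """Ranges where the conditional Gaussian density exceeds the overall one.

    Density equality ``N(mu1, s1)(x) = N(mu2, s2)(x)`` is a quadratic for
    unequal sigmas (two roots, interval or pair of half-lines depending on
    which side the conditional dominates) and a single midpoint crossing for
    equal sigmas.  Equal distributions have no crossing: the full range is
    returned, flagged non-discriminative.
    """
    if overall.degenerate or conditional.degenerate:
        raise DegenerateInputError("gaussian intersection needs sigma > 0 on both sides")
    mu1, s1 = overall.mu, overall.sigma
    mu2, s2 = conditional.mu, conditional.sigma

    if abs(s1 - s2) <= 1e-12 * max(s1, s2):
        if mu1 == mu2:
            return IntervalSet(((-_INF, _INF),), setup="gaussian", discriminative=False)
        x_star = (mu1 + mu2) / 2.0
        # probe one unit past the crossing to find the conditional-dominant side
        probe = x_star + (abs(x_star) + 1.0)
        if conditional.pdf(probe) > overall.pdf(probe):
            return IntervalSet(((x_star, _INF),), setup="gaussian")
        return IntervalSet(((-_INF, x_star),), setup="gaussian")

    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2) + math.log(s2 / s1)
    disc = b * b - 4 * a * c
    if disc <= 0:
        # tangency or no real crossing: no region of strict dominance
        return IntervalSet(((-_INF, _INF),), setup="gaussian", discriminative=False)
    sq = math.sqrt(disc)
    # numerically stable quadratic roots
    q = -0.5 * (b + math.copysign(sq, b))
    r1, r2 = sorted((q / a, c / q))
    r1 = _polish_root(r1, overall, conditional)
    r2 = _polish_root(r2, overall, conditional)
    if r1 > r2:
        r1, r2 = r2, r1

    mid = 0.5 * (r1 + r2)
    if conditional.pdf(mid) > overall.pdf(mid):
        return IntervalSet(((r1, r2),), setup="gaussian")
    return IntervalSet(((-_INF, r1), (r2, _INF)), setup="gaussian")
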