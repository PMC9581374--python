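"""Seeded synthetic fixtures with planted discriminative patterns.

The generator emulates the situation the assessment targets: a categorical
predictor matrix in which a subset of rows carries a fixed column->category
descriptor (the planted subspace pattern), and a numerical outcome whose
distribution shifts on exactly those rows.  Because the true background and
conditional outcome densities are known Gaussians, the analytic intersection
of the *true* densities is returned alongside the sampled data as ground
truth, separating estimation error from inference error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import DataError, DataMatrix, OutcomeVector, Pattern
from .distributions import GaussianPdf, IntervalSet, gaussian_intersection

__all__ = ["PlantSpec", "generate", "worked_example_fixture"]

_INF = float("inf")


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one planted-pattern dataset.

    Defaults describe a moderately sized tabular study: 200 observations,
    four categorical predictors with five levels each, a three-column planted
    descriptor covering 15% of rows, background outcomes N(0, 1) and planted
    outcomes N(3, 1) -- a three-sigma shift, comfortably detectable but not
    trivial.  Background categories are drawn uniformly, so rows outside the
    plant can match the descriptor by chance (probability 5^-3 per row).
    """

    n_rows: int = 200
    n_cols: int = 4
    n_categories: int = 5
    n_pattern_cols: int = 3
    mu0: float = 0.0
    sigma0: float = 1.0
    mu1: float = 3.0
    sigma1: float = 1.0
    planting_fraction: float = 0.15
    seed: int = 0
    descriptor: Optional[Tuple[Tuple[str, str], ...]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.planting_fraction < 1.0):
            raise DataError("planting fraction must be in (0, 1)")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise DataError("sigmas must be positive")
        if self.n_pattern_cols > self.n_cols:
            raise DataError("descriptor cannot span more columns than exist")
        if self.n_planted < 2:
            raise DataError(
                f"planting fraction {self.planting_fraction} yields "
                f"{self.n_planted} planted rows (< 2)"
            )

    @property
    def n_planted(self) -> int:
        return int(round(self.planting_fraction * self.n_rows))

    @property
    def plant_descriptor(self) -> Tuple[Tuple[str, str], ...]:
        if self.descriptor is not None:
            return self.descriptor
        return tuple((f"y{j + 1}", "c0") for j in range(self.n_pattern_cols))


def true_intersection(spec: PlantSpec) -> IntervalSet:
    """Analytic intersection of the two true outcome densities."""
    if spec.mu0 == spec.mu1 and spec.sigma0 == spec.sigma1:
        return IntervalSet(((-_INF, _INF),), setup="gaussian", discriminative=False)
    return gaussian_intersection(
        GaussianPdf(spec.mu0, spec.sigma0, n=2),
        GaussianPdf(spec.mu1, spec.sigma1, n=2),
    )


def generate(spec: PlantSpec) -> Tuple[DataMatrix, Pattern, IntervalSet]:
    """Sample one dataset; fully reproducible from ``spec.seed``.

    Returns the matrix, the planted pattern, and the analytic ground-truth
    range where the true conditional density dominates the true background
    density (the full range, non-discriminative, for a null spec).
    """
    rng = np.random.default_rng(spec.seed)
    cats = np.array([f"c{k}" for k in range(spec.n_categories)], dtype=object)
    cols = [f"y{j + 1}" for j in range(spec.n_cols)]
    cells = rng.choice(cats, size=(spec.n_rows, spec.n_cols))
    planted = np.sort(rng.choice(spec.n_rows, size=spec.n_planted, replace=False))
    descriptor = spec.plant_descriptor
    col_pos = {c: j for j, c in enumerate(cols)}
    for col, cat in descriptor:
        cells[planted, col_pos[col]] = cat
    outcome = rng.normal(spec.mu0, spec.sigma0, size=spec.n_rows)
    outcome[planted] = rng.normal(spec.mu1, spec.sigma1, size=spec.n_planted)
    matrix = DataMatrix(
        pd.DataFrame(cells, columns=cols),
        OutcomeVector("numerical", outcome),
    )
    pattern = Pattern(descriptor=descriptor, label="planted")
    return matrix, pattern, true_intersection(spec)


def worked_example_fixture() -> Tuple[DataMatrix, Pattern]:
    """Five-row fixture with outcomes [1, 3, 4, 5, 7].

    The pattern (column ``y1`` at category ``a``) covers exactly the rows
    whose outcomes are {3, 4, 5}; the empirical setup infers the consequent
    interval [1, 5] from it.
    """
    frame = pd.DataFrame(
        {
            "y1": ["b", "a", "a", "a", "b"],
            "y2": ["u", "v", "u", "v", "u"],
        }
    )
    matrix = DataMatrix(
        frame, OutcomeVector("numerical", np.array([1.0, 3.0, 4.0, 5.0, 7.0]))
    )
    pattern = Pattern(descriptor=(("y1", "a"),), label="worked-example")
    return matrix, pattern
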