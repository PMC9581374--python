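# Methods

## Model and procedure

`discrimint` assesses association rules `φ → c` whose antecedent φ is a
subspace pattern (column→category expectations, optionally given directly as
covered rows) and whose consequent c is either an outcome class or a union of
numeric outcome intervals inferred from the data.

For a numerical outcome z the consequent is the region where the
pattern-conditional density p(z|Φ(φ)) exceeds the overall density p(z|X).
The assumption is that a pattern worth reporting concentrates its
observations' outcomes somewhere; comparing the conditional density against
the overall density — rather than taking the conditional range or a fixed
discretisation — adapts the consequent to each pattern and guards against
both outlier-widened and over-tight intervals.

Two density representations are implemented:

* **Empirical.**  Both pdfs are relative frequencies on the shared support
  (the sorted unique overall outcome values; conditional values absent from
  the sample carry frequency 0).  Intersections are found in O(K) for K
  support values: subtract (overall − conditional), take signs, difference
  the sign vector, and read the nonzero positions.  Each nonzero position i
  maps to the support value at index i, so the lower bound of a dominated
  run sits one support value *before* the first dominated value while the
  upper bound is the last dominated value — the literal index→value mapping
  of the scan.  A tight alternative ("strict mode", off by default) returns
  the dominance runs themselves.  When the conditional pdf starts (ends)
  above the overall pdf, the first (last) bound is −∞ (+∞).  Exact zero
  differences are signed +1, i.e. ties count as overall-dominant; identical
  pdfs therefore produce no crossing and the full range is returned flagged
  non-discriminative.
* **Gaussian.**  Moment fits (population σ, divide-by-n — the sample sizes
  involved make the n vs n−1 distinction immaterial, and the population
  convention keeps `average` and `gaussian` setups consistent).  Density
  equality is a quadratic in z for σ₁ ≠ σ₂; the two real roots bound either
  the conditional-dominant interval or its complement (two half-lines),
  decided by evaluating both densities at the interval midpoint rather than
  by a variance rule so crossed and equal-variance cases are handled
  uniformly.  Equal σ gives the single crossing (μ₁+μ₂)/2.  Roots are
  polished by Newton steps on the log-density difference; every finite bound
  satisfies density equality to well within 1e−9.

The `min_max` and `average` setups use the conditional range and μ±σ
directly.  Consequent membership uses closed bounds on both ends.

Multi-interval empirical consequents are pruned by combined lift: while the
union's lift is below θ and more than one interval remains, the interval
with the lowest individual lift is removed (ties: the one with smaller
consequent coverage, keeping the better-supported interval) and the union
lift is recomputed; if every interval would be removed the original set is
restored, flagged non-discriminative.  Consequent selection (`argmax` /
`threshold` modes) considers the full union plus each single interval; with
more than two intervals the intermediate sub-unions are not enumerated
(combinatorial, and rarely informative beyond the single/union extremes).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `setup` | `empirical` | consequent-inference strategy (`empirical`, `gaussian`, `min_max`, `average`) |
| `theta` (`--lift-threshold`) | 1.3 | minimum combined lift for pruning and for `threshold` selection; 1.3 is the reference decision cutoff for lift itself |
| `mode` | `all` | score the (pruned) union (`all`), the argmax-lift candidate, or every candidate above θ |
| `strict` | off | tight dominance-run bounds for the empirical setup |

Reference flags accompany every report: IG > 0.6, Gini > 0.6, χ² > 3.84 (the
1-df 0.05 critical value; no Yates correction), lift > 1.3, standardised
lift > 0.6, significance < 0.05.  Note that with binary consequents the Gini
impurity reduction is bounded by 0.5, so its 0.6 flag is unreachable there;
it is retained for consistency of the reference row.

## Statistical significance of a pattern

The significance measure scores the pattern's occurrence, not the rule: with
p_φ = ∏ over descriptor columns of the column-marginal frequency of the
expected category, the p-value is the one-sided binomial tail
P(X ≥ Φ(φ)), X ~ Binomial(N, p_φ).  It is therefore constant across
consequent choices for a given pattern, and undefined for patterns supplied
only as explicit row sets (no expectation model).  Entropy/Gini use base-2
logarithms so both gains live in [0, 1].  Metrics with vanishing
denominators are reported as explicit *undefined* markers, never as 0 or
NaN, and never abort a batch.

## Synthetic fixtures

The generator plants a descriptor over 3 of 4 categorical predictors
(5 levels each) in a 200-row matrix, covering 15% of rows — coverage and
dimensionality in the range typical of patterns mined from small clinical
and bioprocess tables.  Planted rows draw outcomes from N(3, 1) against a
N(0, 1) background (a 3σ shift) in the shift condition, and from the
background distribution in the null condition.  Background categories are
uniform, so a background row can match the descriptor by chance (5⁻³ per
row); this contamination is part of what the assessment must tolerate.  The
ground-truth range is the analytic intersection of the two *true* densities,
separating estimation error from inference error.  What the generator does
not emulate: correlated predictors, non-Gaussian or heteroscedastic
outcomes, missing cells, and multiple overlapping patterns — passing the
recovery tests shows the inference machinery is correct under its own
assumptions, not that real tables meet those assumptions.

## Numerical choices and degenerate inputs

* Empty pattern coverage is a degenerate input: interval inference refuses
  it, and batch assessment records a warning for that pattern and continues.
* A zero-variance conditional (or overall) sample makes the Gaussian setup
  fall back to min_max bounds with a `fallback` flag and a warning.
* The standardised-lift range degenerates when the margins admit a single
  attainable joint count (`max(f+g−N, 1) = min(f, g)`); this is detected on
  the integer counts to avoid float ties, and reported undefined.
* Quadratic roots for the Gaussian intersection use the numerically stable
  formulation plus Newton polishing; a non-positive discriminant (tangency)
  yields the full range flagged non-discriminative.
* Report CSV prints 6 significant digits with "inf"/"-inf" sentinels;
  identical inputs produce byte-identical files.

## Known limitations

* **Selection optimism under the null.**  Lift is evaluated on the same
  sample used to infer the interval, and the interval is by construction
  where the conditional sample is densest.  With no true effect this
  inflates lift by roughly O(1/Φ(φ)): at ~30 covered rows the null mean lift
  is ≈1.18 and ≈20% of replicates reach the 1.3 flag; at ~150 covered rows
  the inflation drops to ≈1.07 and the flag rate to <1% (both measured by
  the seeded null-calibration test).  Small-coverage lift flags should be
  read accordingly, or validated on held-out rows.
* The empirical setup's default bound convention includes one support value
  below each dominated run (the literal scan mapping); strict mode gives the
  tight alternative.  Both are exposed because the dominated-run reading and
  the scan mapping genuinely differ on which bound "discriminates".
* The significance model assumes independent column marginals; correlated
  predictors make p_φ an underestimate and the p-value optimistic.
* Weighted variants of support/confidence/lift named in the wider metric
  taxonomy are not implemented (their weighting scheme is defined in
  external work); they are listed in `UNIMPLEMENTED_METRICS`.

## Test problem sizes

The suite runs entirely on generated data: the five-observation reference
example, hand-built 9-, 20- and 40-row matrices, 200-replicate seeded
recovery/calibration experiments at 200×4, and oracle fuzzing with ~1000
random pdf pairs and ~500 random margins — a few seconds in total.
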