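# discrimint

Discriminative-interval assessment of subspace patterns against numerical and
categorical outcomes.

## The problem

Pattern mining and biclustering on tabular biomedical data (gene expression,
clinical records, metabolic engineering screens) produce *patterns*: sets of
column→category expectations that a subset of observations satisfies.  When a
target variable exists — survival in months, drinks per day, compound
concentration — the question becomes whether a pattern *discriminates* a
range of that outcome.  Classic rule measures (confidence, lift, χ²) assume a
nominal consequent; discretising a numerical outcome in advance imposes rigid
boundaries that rarely match any particular pattern.

`discrimint` instead infers a consequent *tailored to each pattern*: it
compares the outcome distribution of the whole sample, p(z|X), with the
outcome distribution of the pattern's covered rows, p(z|Φ(φ)), and takes the
range(s) where the conditional density exceeds the overall density as the
rule consequent, `φ → ⋃ᵢ [v₁⁽ⁱ⁾, v₂⁽ⁱ⁾]`.  Each rule is then scored with a
suite of interestingness measures on the counts (N, Φ(φ), Φ(c), Φ(φ→c)).

Four setups derive the consequent from the pattern-conditional outcomes:

* **min_max** — `[min, max]`;
* **average** — `[μ−σ, μ+σ]` (population σ);
* **gaussian** — the intersection points of Gaussian fits to the overall and
  conditional outcomes (density equality is a quadratic in z);
* **empirical** — the intersection of the two relative-frequency pdfs on the
  shared support, found in linear time by a sign-change scan; may yield
  several intervals, with half-open intervals (±∞ bounds) when the
  conditional pdf starts or ends above the overall pdf.

Multi-interval empirical consequents are pruned by combined lift: intervals
are dropped lowest-individual-lift first until the union's lift reaches a
threshold θ (default 1.3), resetting to the full set if nothing passes.

The metric registry covers support-, confidence- and lift-based families:
rule/antecedent support, confidence, all/Laplace/casual/descriptive-confirmed
confidence, hyper confidence and hyper lift (hypergeometric), lift,
standardised lift (lift rescaled to [0,1] by its margin-constrained attainable
range), information gain and Gini-impurity reduction, Pearson χ², and a
binomial-tail statistical significance of the pattern against column-marginal
expectations.  Reference decision thresholds (IG > 0.6, Gini > 0.6,
χ² > 3.84, lift > 1.3, standardised lift > 0.6, significance < 0.05) are
reported as flags alongside every value.

## Worked example

A ten-patient echocardiogram-style table, `examples/demo.csv`, with survival in months
as the outcome, and one pattern (`epss=medium` and `lvdd=medium`, covering the
three patients surviving 2–4 months):

```sh
discrimint --data examples/demo.csv --outcome-col survival \
           --patterns examples/demo_patterns.json --distribution gaussian \
           --output demo_report.csv --verbose
```

prints

```
INFO pattern 'mm' -> [0.6281885361636594,5.275396420028711] (lift=3.3333333333333335)
wrote 1 pattern report(s) to demo_report.csv
```

The same run through the library:

```python
from discrimint import read_matrix, read_patterns, assess

matrix = read_matrix("examples/demo.csv", "survival")
(report,) = assess(matrix, read_patterns("examples/demo_patterns.json"), setup="gaussian")
rule = report.rules[0]
print("consequent:", rule.consequent_text)
print("counts:", rule.counts.as_tuple())
for name in ("Lift", "Standardised Lift", "Chi-Squared",
             "Information Gain", "Statistical Significance"):
    print(f"{name}: {rule.metrics[name]:.4g}  flag={rule.flags.get(name)}")
```

```
consequent: [0.6281885361636594,5.275396420028711]
counts: (10, 3, 3, 3)
Lift: 3.333  flag=True
Standardised Lift: 1  flag=True
Chi-Squared: 10  flag=True
Information Gain: 0.8813  flag=True
Statistical Significance: 0.2064  flag=False
```

Reading: the Gaussian intersection of the pattern's survival distribution
with the overall one delineates roughly 0.6–5.3 months.  All three covered
patients fall in that range and no one else does, so lift is 3.33 (the
maximum attainable given the margins — standardised lift 1) and χ² = 10
rejects independence.  The binomial significance of the *pattern itself*
(0.21) says a coverage of 3 is unsurprising given the column marginals — the
pattern is discriminative but not rare.

Categorical outcomes skip interval inference: every class is scored and the
best class by lift is reported.  See `discrimint --help` for the remaining
options (`--mode argmax|threshold` for consequent selection among single
intervals and their union, `--strict-intervals` for tight dominance-run
bounds, `--lift-threshold` for θ).

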