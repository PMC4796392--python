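# mmcompare

Statistical comparison of prediction methods for computational chemistry and
virtual screening: are two (or more) scoring methods actually different, once
the correlation between them is taken into account?

The library covers:

- **Pairwise machinery** (`mmcompare.pairwise`) — variance of a difference
  with correlation (`var_A + var_B - 2 r sd_A sd_B`), paired/pooled/Welch t
  statistics, asymmetric error-bar combination in quadrature (independent or
  correlated), the `(ΔN)² > 4N` yes/no split rule, and overlap-based verdicts
  (`different` / `not_different` / `indeterminate`).
- **ROC statistics** (`mmcompare.roc`) — AUC with its indicator matrix,
  DeLong-style placement variance, correlation-aware standard errors for AUC
  differences, ROC enrichment at an inactive fraction *f* (E = g/f), the
  slope approximation `E (1 + ln E / ln f)`, and enrichment-difference error
  bars (two covariance conventions, see below).
- **Correlation comparison** (`mmcompare.correlation`) — Fisher z intervals
  for Pearson r, independent z tests, the metric triangle bounds on the
  inter-method correlation, the product rule `<r_yz> ≈ r_xy r_xz`, the
  classical covariance of two correlation coefficients sharing a reference,
  and dependent-difference intervals built from correlated asymmetric bars.
- **Family-wise comparison** (`mmcompare.multi`) — FWER arithmetic,
  Holm–Bonferroni (step-down) and Hochberg (step-up), paired chi-squared over
  categories, one-way ANOVA with the nested-model F reading, adjusted r²,
  covariance whitening (`W = V^{-1/2}` by eigendecomposition) and the
  correlated chi-squared statistic, Tukey HSD against the studentized-range
  quantile, and an equivalence-grouping layout (columns of statistically
  indistinguishable methods, dotted edges across columns).
- **Effect sizes and Bayes** (`mmcompare.effect`) — Cohen's d (with the
  sum-of-variances denominator as default), probability of superiority
  (linear `0.25 d + 0.5` and exact `Φ(d/√2)`), the diagnostic-test posterior,
  the minimum Bayes odds-ratio `−1/(e p ln p)`, and a flat/tabulated-prior
  posterior density over a true difference.
- **Synthetic data** (`mmcompare.simulate`) — the two-predictor noise model
  (independent or shared noise streams), trivariate-normal correlation
  replicates, binormal score-set pairs with a correlation knob, Gaussian
  performance matrices with prescribed covariance, and the small worked
  8-active/10-inactive screening fixture.

## CLI

Everything is exposed through the `mmc` command; all subcommands emit a JSON
report (schema in `src/mmcompare/report_schema.json`):

```bash
mmc pair --a a.txt --b b.txt --paired            # paired mean comparison
mmc roc --scores scores.csv --label-col label --methods m1,m2 \
        --metric enrichment --fraction 0.2 --cov-mode worked-example
mmc rcompare --summary 0.9 0.8 0.72 50           # dependent r comparison
mmc rcompare --data table.csv --ref-col x --method-cols y,z
mmc multi --matrix perf.csv --test anova         # also hsd, holm, hochberg,
                                                 # chi2, correlated-anova
mmc layout --matrix perf.csv --out layout.svg    # grouping depiction
mmc effect --a a.txt --b b.txt
mmc bayes --p 0.05
mmc diagnostic --prev 0.02 --power 0.9 --alpha 0.05
mmc simulate --model predictors --reps 10000 --seed 42 --out sim.csv
```

Score tables are CSV/TSV with a 0/1 label column; performance matrices are
CSV/TSV with system labels in the first column and one method per remaining
column.

## Conventions worth knowing

- Sample variances use the unbiased (n−1) denominator throughout.
- Enrichment-difference covariances have two modes: `definition` (mean joint
  indicator minus product of means — the only convention that gives SE = 0
  for identical methods, and the default) and `worked_example`
  (joint-selection fraction × geometric mean of variances, which reproduces
  the traditional printed arithmetic). They disagree slightly by
  construction.
- Dependent correlation intervals combine r-space half-widths (a z-space
  variant exists but is not the default).
- Near-singular covariances are whitened after flooring tiny eigenvalues;
  all clipping/flooring/relabelling events surface as warnings in reports.
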