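# tas-masem

Two-stage meta-analytic structural equation modeling (MASEM/TSSEM) of the
20-item Toronto Alexithymia Scale (TAS-20).

The TAS-20 is the standard self-report measure of alexithymia — difficulty
identifying feelings (DIF), difficulty describing feelings (DDF), and an
externally oriented thinking style (EOT) — and its internal structure has
been contested for decades: unidimensional, two- and three-factor variants,
bifactor representations, and models that add a method factor or correlated
residuals for its five reverse-worded items. This package implements the
meta-analytic machinery needed to adjudicate among those structures from
published study summaries, for psychometricians and meta-analysts who have
item-level correlation matrices or reported factor solutions, not raw data.

## What it computes

**Stage 1 — fixed-effects pooling.** Each of k study samples contributes a
20×20 Pearson correlation matrix, either directly or reconstructed from a
reported factor solution as the model-implied correlations Λ Φ Λᵀ (loadings
suppressed below a reporting threshold, typically .40, are imputed as zero).
The unique correlations are pooled as sample-size-weighted means,

    r̄_jk = Σᵢ nᵢ r_ijk / Σᵢ nᵢ ,

and the normal-theory (Olkin–Siotani) asymptotic covariance V of the 190
pooled correlations is evaluated at the pooled values with N = Σ nᵢ.

**Stage 2 — weighted least squares CFA.** Each competing measurement model
parameterizes the implied correlation vector ρ(θ) through Λ, Φ and optional
residual correlations Θ, and is estimated by minimizing

    F(θ) = (r − ρ(θ))ᵀ V⁻¹ (r − ρ(θ)) ,

whose minimum serves as the model χ². The catalog covers the nine standard
competing structures (unidimensional; DIF/DDF–EOT; the original DIF–DDF–EOT;
two alternative three-factor assignments; the four-factor DIF–DDF–PT–IOE;
a bifactor model; a nested method factor over the reverse-keyed items; and a
correlated-trait–correlated-uniqueness model), each reported with CFI, RMSEA
(90% CI by noncentral-χ² inversion), SRMR, AIC = χ² − 2df, BIC = χ² − ln(N)df,
and McDonald's ω = (Σλ)²/((Σλ)² + Σψ) per subscale.

Around the two stages the package provides exploratory factor-number
criteria (Velicer's MAP, Horn's parallel analysis, sample-size-adjusted BIC,
sequential χ² tests), the top-down "bass-ackwards" hierarchy of
varimax-rotated principal components linked by component-score correlations,
configural measurement-invariance comparisons across languages and clinical
status (per-group fits and loading differences Δλ against a reference
group), and a seeded synthetic-corpus generator that emulates the published
evidence base (88 samples, median n = 327, censored EFA patterns, per-language
loading perturbations) so that every stage is testable without any download.

## Worked example

```python
from tas_masem import default_population, generate_corpus, pool, summarize
from tas_masem.pipeline import fit_all_models, comparison_table

records, truth = generate_corpus(default_population(seed=1))
print(summarize(records).k)          # 88 samples
pooled = pool(records)
fits = fit_all_models(pooled, ["1", "2", "3a", "5", "6", "7"], seed=1)
print(comparison_table(fits)[["chi2", "df", "cfi", "rmsea", "srmr"]].round(3))
print(fits["3a"].factor_corr.round(2))
```

prints (seed 1, total N = 53,109):

```
            chi2   df    cfi  rmsea   srmr
model
1      20371.459  170  0.772  0.047  0.086
2       8476.223  169  0.906  0.030  0.041
3a      2299.316  167  0.976  0.016  0.019
5       2139.628  150  0.978  0.016  0.018
6        339.713  162  0.998  0.005  0.009
7        337.821  157  0.998  0.005  0.009

      DIF   DDF   EOT
DIF  1.00  0.74  0.26
DDF  0.74  1.00  0.43
EOT  0.26  0.43  1.00
```

Reading the comparison: the unidimensional model (row 1) is untenable; the
original three-factor model (3a) fits well; and the models that absorb the
reverse-keying method variance (6, nested method factor; 7, correlated
residuals) fit best — the corpus was generated with a .15 residual
correlation among the reverse-worded items, which model 3a cannot absorb.
The fitted factor correlations recover the generating values (.77/.47/.32)
up to the group perturbations the generator plants in translated versions.

The same workflow is available from the shell:

```
tas-masem simulate --out corpus/ --seed 1
tas-masem fit corpus/coding_sheet.csv --all-models
tas-masem efa corpus/coding_sheet.csv
tas-masem invariance corpus/coding_sheet.csv --by language --reference English
tas-masem run-full --out-dir run/ --seed 1
```

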