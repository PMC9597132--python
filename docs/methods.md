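# Methods

## The two-stage estimator

The package treats the evidence base as k independent samples from (under
the fixed-effects assumption) one common population correlation matrix of
the 20 TAS-20 items. Stage 1 estimates that matrix; stage 2 fits structural
models to it with weights that reflect its sampling uncertainty. Fitting a
structural model directly to a pooled correlation matrix as if it were an
observed sample matrix is known to be inaccurate; carrying the asymptotic
covariance of the pooled correlations into the stage-2 discrepancy is what
makes the two-stage approach valid.

**Pooling.** Each unique correlation is the sample-size-weighted mean of
the study correlations (weights nᵢ; the difference against nᵢ−1 weighting
is negligible at these sizes and the choice is pinned in code). The
equivalent equality-constrained multigroup ML formulation converges to the
same point for correlation inputs; the closed form is used because it is
exact, fast, and directly testable. No random-effects variant is provided —
between-study heterogeneity is instead surfaced by the per-group refits of
the invariance module.

**Reconstruction.** Studies that report only a factor solution enter
through the model-implied correlations Λ Φ Λᵀ with the diagonal forced to 1.
Unique variances are never needed because only off-diagonals enter pooling.
Censored loadings (suppressed below a reporting threshold, typically .40)
are imputed as zero before the product; this is the standard practice for
meta-analytic factor patterns and is essentially unbiased at the pooled
level. Implied magnitudes above 1 (possible with oblique reported patterns)
are clipped to ±.999 with a warning. Oblique patterns are assumed to be
pattern (not structure) coefficients accompanied by their factor
correlations; solutions without factor correlations are treated as
orthogonal.

**Asymptotic covariance.** The normal-theory covariance of Pearson
correlations (Olkin–Siotani/Pearson–Filon form) is evaluated at the pooled
matrix and scaled by 1/ΣN, giving the familiar diagonal (1 − ρ²)²/N. It is
evaluated at the pooled values — not per study — so that the weights match
the point at which the stage-2 discrepancy is evaluated. The exact variant
implemented is pinned by a Monte-Carlo test (4 variables, n = 2,000, 20,000
replicate datasets, agreement within 3 Monte-Carlo standard errors), not by
citation.

## The WLS engine

Models are declared as constraint sets: an item→factor partition with all
assigned loadings free, unit-variance factors (so the solution is
standardized and loadings are directly comparable across groups), free
correlations among content factors, and optional overlays — a general
factor over all items, a method factor over the five reverse-worded items
(both orthogonal to everything), or free residual correlations. The
implied diagonal is fixed at 1, so uniquenesses are derived (ψ = 1 − h²),
never estimated; degrees of freedom are 190 minus the free-parameter count,
audited model-by-model against the published fit table.

Minimization uses a trust-region-reflective least-squares solver on the
whitened residual A⁻¹(r − ρ(θ)) (A the Cholesky factor of V), with an
analytic Jacobian assembled from dΣ/dλ, dΣ/dφ, dΣ/dθ. Start values are
.5 for loadings, .3 for factor correlations, 0 for residual correlations,
with four additional jittered starts (uniform ±.1, seeded); the best
minimum is kept. Convergence requires solver success plus a gradient
inf-norm below 1e-4 relative to max(1, χ²); loadings are bounded at ±2 and
correlations at ±.999, and solutions implying |λ| > 1 or h² > 1 raise a
Heywood flag rather than an error. χ² is the discrepancy minimum itself
(V already carries 1/N). CFI uses the independence model fitted to the same
input (closed form r V⁻¹ r on 190 df) with an ε = 1e-10 floor against 0/0
at perfect fit; RMSEA is √(max(χ²−df,0)/(df(N−1))) with a 90% CI from
noncentral-χ² inversion by bracketed root finding, flagged "not computable"
instead of erroring when the inversion fails; SRMR is the RMS of the 190
raw residuals; AIC = χ² − 2df and BIC = χ² − ln(N)df; ω per subscale is
(Σλ)²/((Σλ)² + Σψ) over that factor's items.

## Exploratory tooling

MAP uses squared partial correlations after partialling successive
principal components (the original formulation; a fourth-power variant is a
one-line change but is not exposed). Parallel analysis uses the
mean-eigenvalue rule over 100 seeded replications of standard-normal data
at the full pooled N; a quantile rule is available via an argument. The
sample-size-adjusted BIC is χ² − df·ln((N+2)/24) over ML factor solutions
(statsmodels estimation; χ² with the standard Bartlett-style correction),
and the sequential test takes the smallest m whose exact-fit test is
non-significant at α = .05 (an exact-fit, not difference-test, convention;
the difference-test variant was considered and rejected as redundant with
the SABIC trace). The bass-ackwards hierarchy uses principal components —
not common factors — with varimax rotation, matching how such hierarchies
are usually displayed; component scores are regression scores W = R⁻¹Λ
scaled to unit variance, which makes within-level score correlations
exactly zero and gives the cross-level linking correlations WₗᵀRWₗ₊₁.
Each component's largest-magnitude loading is made positive, so output is
deterministic. The default depth is 4 levels, the depth at which the
DIF/DDF blend finally separates; edges below |r| = .30 are omitted from
the exported graph and edges below .50 are styled dashed.

## The synthetic corpus

The generator emulates the published evidence base: 88 samples across 16
language versions (34 English), lognormal sample sizes with median 327 and
dispersion σ = 1.2 truncated to [99, 12,706] (a lognormal cannot match the
published minimum and maximum simultaneously; σ was set once so that k = 88
lands near the published total N ≈ 70,000 in expectation), about a quarter
clinical samples, and a reporting mix of 3% raw correlation matrices, 31%
censored oblique EFA patterns, and 66% CFA patterns. The population is the
three-correlated-factor structure with loadings .32–.75 (weakest for the
reverse-keyed EOT items), factor correlations .77/.47/.32, and a .15
residual correlation among all pairs of reverse-worded items — values that
imply subscale reliabilities near the published .84/.75/.62. Translated
versions receive fixed additive loading shifts of .05–.20 concentrated on
items 5 and 12, and clinical samples a +.20 shift on item 10, sized so mean
absolute loading differences fall in the published .06–.11 range.

Because coding takes the richest solution a study reports, pattern-based
records must carry the reverse-keying method variance or the pooled matrix
would understate it: EFA studies therefore report four-factor quartimin
patterns (censored at .40) and CFA studies the three-factor model with the
nested method factor, fitted per study by unweighted least squares and
clipped to the admissible range. A uniform residual correlation of ρ among
five items is exactly a rank-one method factor with loadings √ρ, so this
reporting preserves the planted structure.

What the generator does *not* emulate: ordinal/Likert response scales (data
are multivariate normal, matching the use of Pearson correlations
throughout), publication bias, overlapping samples, skewed symptom
distributions, missing items, and study-level covariates beyond language
and clinical status. Passing tests therefore demonstrate the estimator's
correctness under the model's own assumptions, not robustness to ordinal
coarseness or selection effects.

One measured consequence of the calibration: with most EOT loadings below
the .40 censor threshold, a single censored EFA pattern loses much of the
EOT block (reconstruction RMS error ≈ .07 against the uncensored
reconstruction). The tests freeze this as a monitored ceiling; the
end-to-end recovery tests confirm the pooled estimates remain accurate
because censored EFA patterns are a minority of the (n-weighted) corpus.

## Problem sizes used by the tests and acceptance script

Parameter recovery runs on a 30-sample raw-correlation corpus with total
N ≈ 30,000 (loadings and factor correlations recovered within ±.02; the
replicate-bias check averages 12 such corpora at total N ≈ 12,000 each).
The residual-correlation recovery uses 40 samples at total N ≈ 50,000.
The Monte-Carlo check of the correlation covariance uses 20,000 simulated
datasets of n = 2,000 on four variables. The acceptance script generates
the full 88-sample corpus, fits all nine models, and runs the exploratory
and invariance analyses in one pass. These sizes are the package's own
choices: large enough that sampling error is well below the asserted
tolerances, small enough to keep the whole suite quick on one core.

## Known limitations

- Fixed-effects pooling only; heterogeneity appears solely through the
  per-group refits, with no τ² quantification.
- Invariance testing is configural and descriptive (separate per-group
  fits, Δλ against a reference); equality-constrained simultaneous
  estimation is a declared extension point, not implemented.
- No robust (mean/variance-adjusted) WLS corrections and no modification
  indices; the engine targets correlation matrices, never raw data.
- The PT/IOE sub-facet assignment and the alternative three-factor
  assignment ship as configuration flagged for verification against the
  original structural diagrams; the degrees-of-freedom audit constrains
  only the partition sizes, not the specific item placement.
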