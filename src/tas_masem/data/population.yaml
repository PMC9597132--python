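# Default population for the synthetic meta-analytic corpus.
#
# A three-correlated-factor world (DIF, DDF, EOT) with weak residual
# correlations among the five reverse-worded items and small per-language
# loading shifts for the translated versions.  Loading bands: DIF .60-.75,
# DDF .55-.68, EOT .32-.50 with the reverse-keyed items weakest; factor
# correlations .77/.47/.32.  These values imply subscale reliabilities
# omega of roughly .86/.76/.63.

loadings:          # item -> primary standardized loading
  1: 0.68
  2: 0.66
  3: 0.72
  4: 0.55
  5: 0.32
  6: 0.60
  7: 0.75
  8: 0.50
  9: 0.63
  10: 0.42
  11: 0.62
  12: 0.68
  13: 0.70
  14: 0.66
  15: 0.48
  16: 0.40
  17: 0.58
  18: 0.38
  19: 0.40
  20: 0.45

factor_correlations:    # order DIF, DDF, EOT
  - [1.00, 0.77, 0.32]
  - [0.77, 1.00, 0.47]
  - [0.32, 0.47, 1.00]

residual_correlation: 0.15     # among all pairs of reverse-keyed items

k: 88
n_median: 327
n_sigma: 1.2                   # lognormal dispersion, truncated to n_range
n_range: [99, 12706]

reporting_mix:                 # proportions of source kinds
  raw_correlations: 0.034
  efa_pattern: 0.307
  cfa_pattern: 0.659
censor_threshold: 0.40         # reverse of reporting: EFA loadings below
                               # this magnitude are suppressed by "authors"

# Coding takes the richest solution a study reports, so pattern-based
# records carry the keying-method variance: EFA studies report a
# four-factor oblique pattern, CFA studies the three-factor model with
# the nested method factor over the reverse-keyed items.
efa_factors: 4
cfa_reported_model: "6"

languages:                     # samples per language version
  English: 34
  French: 8
  German: 7
  Farsi: 6
  Portuguese: 5
  Japanese: 5
  Turkish: 4
  Spanish: 4
  Korean: 3
  Dutch: 3
  Italian: 2
  Finnish: 2
  Chinese: 2
  Swedish: 1
  Hindi: 1
  Arabic: 1

clinical:
  english_clinical_samples: 5  # exact count among the English samples
  other_clinical_rate: 0.28    # probability elsewhere
  perturbation: {10: 0.20}     # clinical groups load higher on item 10

# Additive shifts on primary loadings for translated versions, sized so
# that mean absolute loading differences fall in the .05-.11 range.
group_perturbations:
  French: {5: 0.10, 12: -0.12, 17: -0.05}
  German: {5: 0.14, 12: -0.15, 3: -0.10, 8: -0.08}
  Farsi: {5: 0.18, 12: -0.08}
  Portuguese: {5: 0.20, 12: -0.18, 11: 0.08}
  Japanese: {5: 0.12, 16: -0.10, 19: -0.12}
  Turkish: {5: 0.10, 12: -0.08}
  Spanish: {5: 0.08, 12: -0.06}
  Korean: {5: 0.10, 16: -0.08}
  Dutch: {12: -0.06}
  Italian: {5: 0.10}
  Finnish: {12: -0.08}
  Chinese: {5: 0.12, 15: -0.10}
  Swedish: {}
  Hindi: {5: 0.10}
  Arabic: {12: -0.10}
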