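# TAS-20 item scheme and competing measurement-model configurations.
#
# Items are referred to by their position in the standard 20-item form.
# The five reverse-worded items (scored so that agreement indicates LOW
# alexithymia before recoding) are 4, 5, 10, 18, 19; four of them sit on
# the externally-oriented-thinking (EOT) factor.
#
# The PT/IOE sub-facet split of EOT (models 3b/4) and the alternative
# assignment of model 3c are transcribed from published structural
# diagrams of the instrument; verify against the original figure before
# relying on per-item output for those models.  The degrees-of-freedom
# audit in model_catalog depends only on the partition sizes and is
# checked against the published fit table.

n_items: 20
negative_keyed: [4, 5, 10, 18, 19]

partitions:
  one_factor:
    ALEX: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  two_factor:
    DIF/DDF: [1, 2, 3, 4, 6, 7, 9, 11, 12, 13, 14, 17]
    EOT: [5, 8, 10, 15, 16, 18, 19, 20]
  three_factor:
    DIF: [1, 3, 6, 7, 9, 13, 14]
    DDF: [2, 4, 11, 12, 17]
    EOT: [5, 8, 10, 15, 16, 18, 19, 20]
  three_factor_pt_ioe:
    DIF/DDF: [1, 2, 3, 4, 6, 7, 9, 11, 12, 13, 14, 17]
    PT: [8, 15, 16, 20]
    IOE: [5, 10, 18, 19]
  three_factor_eot_ioe:   # labels retained, items assigned differently
    DIF/DDF: [1, 2, 3, 4, 6, 7, 9, 11, 12, 13, 14, 17]
    EOT: [5, 8, 15, 16, 20]
    IOE: [10, 18, 19]
  four_factor:
    DIF: [1, 3, 6, 7, 9, 13, 14]
    DDF: [2, 4, 11, 12, 17]
    PT: [8, 15, 16, 20]
    IOE: [5, 10, 18, 19]

models:
  "1":
    description: Unidimensional model (Alex)
    partition: one_factor
    correlated: true
  "2":
    description: Two-dimensional model (DIF/DDF-EOT)
    partition: two_factor
    correlated: true
  "3a":
    description: Original three-dimensional model (DIF-DDF-EOT)
    partition: three_factor
    correlated: true
  "3b":
    description: Alternative three-dimensional model (DIF/DDF-PT-IOE)
    partition: three_factor_pt_ioe
    correlated: true
  "3c":
    description: Alternative three-dimensional model (DIF/DDF-EOT-IOE)
    partition: three_factor_eot_ioe
    correlated: true
  "4":
    description: Four-dimensional model (DIF-DDF-PT-IOE)
    partition: four_factor
    correlated: true
  "5":
    description: Bifactor model with three original factors as nested factors
    partition: three_factor
    correlated: false
    general_factor: true
  "6":
    description: Original three-dimensional model + nested method factor
    partition: three_factor
    correlated: true
    method_factor: negative_keyed
  "7":
    description: Original three-dimensional model + correlated residuals
    partition: three_factor
    correlated: true
    residual_correlations: negative_keyed

# Re-parameterized bifactor with DDF as the reference factor (no specific
# DDF factor); available behind the include_variants flag.
variants:
  "5b":
    description: Bifactor model with DDF as reference factor
    partition: three_factor
    correlated: false
    general_factor: true
    drop_specific: [DDF]
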