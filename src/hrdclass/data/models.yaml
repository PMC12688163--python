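# Model registry: feature blocks and the seven model configurations.
#
# The five primary models hold 9 / 14 / 16 / 25 / 30 features. The published
# reference decision thresholds are recorded as metadata only; a freshly
# trained classifier always calibrates its own threshold by LOOCV max-F1.
#
# The retained-feature lists per block are the registry's documented default
# (the within-block screen/prune outcome is cohort-dependent); override with
# a custom registry file to change them.
blocks:
  CNA:
    - cna_burden
    - cna_load
    - macn
    - td_score
    - chromothripsis_score
    - CX1
    - CX2
    - CX3
    - CX5
  ASCN:
    - scarHRD
    - CN1
    - CN2
    - CN9
    - CN17
  SNV:
    - SBS1
    - SBS3
    - SBS5
    - SBS6
    - SBS8
    - SBS13
    - SBS18
    - SBS30
    - ID1
    - ID2
    - ID4
    - ID5
    - ID6
    - ID8
    - ID9
    - ID11

models:
  CNA:
    blocks: [CNA]
    reference_threshold: 0.382
  ASCN:
    blocks: [CNA, ASCN]
    reference_threshold: 0.450
  SNV:
    blocks: [SNV]
    reference_threshold: 0.344
  SNV+CNA:
    blocks: [SNV, CNA]
    reference_threshold: 0.296
  SNV+ASCN:
    blocks: [SNV, CNA, ASCN]
    reference_threshold: 0.374
  no_scarHRD:
    blocks: [CNA, ASCN]
    exclude: [scarHRD]
  scarHRD_only:
    features: [scarHRD]
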