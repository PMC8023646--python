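# Full-pipeline run on a synthetic cohort with the default study structure.
out_dir: microrem_run
simulate:
  n_subjects: 110
  responder_fraction: 0.4
  n_genera: 60
  n_beneficial: 5
  n_detrimental: 5
  effect_fold: 2.0
  overdispersion: 1.0
  lps_coupling: -0.5
alpha: 0.05
lda_threshold: 2.0
k_folds: 10
n_trees: 1000
top_m: 10
rf_variants: [classic, microbiome, combined]
mda_variant: microbiome
adjustment_sets: [primary, extended]
seed: 1
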