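# Desk-scale demo of the full pipeline (~1 minute on one CPU).
# Full-scale analyses raise the simulate sizes and restore the scan
# defaults (wgr_iters: 20000, rfr_trees: 10000, rfr_permutations: 1000).
seed: 5
trait: trait
simulate:
  n_families: 2
  n_ril_per_family: 40
  n_chrom: 2
  markers_per_chrom: 50
  n_environments: 2
  h2_additive_target: 0.35
  h2_epistatic_target: 0.05
  missing_rate: 0.02
qc:
  maf_min: 0.05
gwas:
  methods: [mlm, wgr, rfr]
  wgr_iters: 800
  wgr_burnin: 100
  rfr_trees: 50
  rfr_mtry: 10
  rfr_permutations: 5
cv:
  schemes: [across_family]
  models: [GBLUP]
  folds: 5
  reps: 2
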