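# Bulk demo: two simulated platforms, planted response genes, full chain
# simulate -> harmonize -> cross-validated DE selection -> classifier CV.
seed: 7
stages: [simulate, harmonize, cvdea, evaluate]
simulate:
  n_datasets: 2
  genes: 2000
  samples_per_dataset: 100
  platform_per_dataset: [intensity, count]
  planted_genes:
    - [0, 1.5]
    - [1, -1.5]
    - [2, 1.5]
    - [3, -1.5]
    - [4, 1.5]
    - [5, -1.5]
    - [6, 1.5]
    - [7, -1.5]
    - [8, 1.5]
    - [9, -1.5]
cvdea:
  folds: 10
  keep: 8
  mean_p: 0.05
  subset_datasets: [d0]
evaluate:
  methods: [l2_logistic]
  tune_iters: 20
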