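# Spatial demo: paired tumor/stroma cohort with planted compartment markers
# and injected QC failures; QC -> mixed models -> bootstrap consensus.
seed: 9
stages: [simulate_spatial, spatial_qc, spatial_fit]
simulate_spatial:
  n_patients: 40
  targets: 150
  planted_tumor_genes: [[0, 2.0], [1, -1.5], [2, 1.5]]
  planted_stroma_genes: [[3, 2.0], [4, -1.5], [5, 1.5]]
  planted_opposing_genes: [[6, 1.5], [7, -1.5]]
  patient_intercept_sd: 0.5
  qc_fail_segment_fraction: 0.1
  qc_fail_probe_fraction: 0.02
spatial_fit:
  bootstrap: 5
  q: 0.05
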