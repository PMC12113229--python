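# Desk-scale demo: full pipeline on a 128x128 synthetic landscape.
seed: 1
output_dir: outputs
grid_shape: [128, 128]
cell_size: 30.0
n_presences: 200
species:
  focal_pheasant: {}
  silver_pheasant: {}
  grey_laughingthrush: {}
  necklaced_laughingthrush: {}
esdm:
  n_rounds: 10
  auc_gate: 0.8
  train_fraction: 0.8
overlap_threshold: 0.7
marxan:
  target: 0.5
  spf: 16.74
  blm: 2.11
  n_runs: 200          # scaled down from 1000 repeat runs
  n_iterations: 20000
  unit_area_km2: 0.1   # scaled to the ~14.7 km2 synthetic extent
  key_threshold: 0.9
  contiguity: true
  min_units: 2
  focal_species: focal_pheasant
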