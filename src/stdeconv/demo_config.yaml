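# Demo pipeline configuration: small enough to run end-to-end on one CPU
# in well under a minute, while exercising every stage.
seed: 0
output_dir: stdeconv_demo_out
log_level: WARNING

reference:
  n_types: 4
  n_genes: 120
  cells_per_type: 60
  n_markers_per_type: 10
  base_mean: 2.0
  marker_fold: 5.0
  dispersion: 2.0

spots:
  n_spots: 200
  cells_min: 8
  cells_max: 12
  dirichlet_alpha: 1.0
  max_types_per_spot: 3
  n_spatial_clusters: 4
  grid_side: 100.0
  jitter_sd: 3.0

real_spots:
  seed_offset: 1000
  library_scale: 1.5

preprocess:
  p_threshold: 0.005

zones:
  auto: structured

network:
  d_emb: 32

train:
  rounds: 3
  lambda_mmd: 0.0
  use_dann: true
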