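# Packaged small end-to-end configuration: 6 subjects per group on a
# 12 x 12 x 8 voxel grid with 8 planted sources and 8 estimated
# components, on a shortened run (20 trials per block).
seed: 7
out_dir: nback_ica_out
simulation:
  grid_dims: [12, 12, 8]
  n_sources: 8
  n_subjects_per_group: 6
  tr_seconds: 2.0
  trials_per_block: 20
  scans_per_condition: 40
  noise_sd: 1.0
  drift_amplitude: 0.5
  hrf_delay_jitter_sd: 0.3
  coupling_strength: 0.0
ica:
  n_components: 8
  n_runs: 4
behavior:
  exclusion_rule: either
stats:
  alpha: 0.05
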