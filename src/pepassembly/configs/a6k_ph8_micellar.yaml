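# A6K (H2N-AAAAAAK-OH) at pH 8.0: charge state, synthetic ensemble, turns, aggregates
sequence: AAAAAAK
n_term_free: true
c_term_free: true
ph_values: [8.0]
pka_set: bjellqvist
generator:
  n_chains: 12
  box_nm: 8.0
  placement: micellar
  min_dist_A: 4.0
  seed: 2017
  motif: beta_turn_II
  n_frames: 3
turn_criteria:
  ca_dist_max: 7.0
  hbond_ON_max: 3.5
  hbond_angle_min: 120.0
  combine: either
  exclude_helix: true
cluster_cutoff_A: 4.5
dielectric: 78.5
coulomb_cutoff_nm: 1.4
output_dir: pepassembly_run_ph8
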