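# Example chapfold run: ubiquitin + 5 uM DnaJ, quench-time and
# extended-time sweeps, binding-constant fit.
# Units: seconds, piconewtons, molar; rates in 1/s or 1/(M s); lengths nm.

seed: 1
log_level: INFO
output_dir: chapfold_results

scheme:
  k_u: 0.93              # unfolding rate at the 120-pN reference force
  k_c: 10.0              # collapse rate on force quench
  k_f0: 0.52             # folding rate from the collapsed state
  k_uc: 50.0             # re-extension rate of collapsed states under force
  k_on_ext: 4.55e4       # DnaJ association to the extended state
  k_off_ext: 4.28e-2     # DnaJ dissociation from the extended state
  chaperone_conc: 5.0e-6
  fold_competence: 0.75  # long-quench plateau of the refolding yield
  free: [k_on_ext, k_off_ext]

protocol:
  unfold_force_pn: 120.0
  unfold_s: 5.0
  t_ext_default: 0.0
  t_q_default: 5.0
  test_s: 5.0
  t_q_grid: [0.5, 1, 2, 5, 10, 15]
  t_ext_grid: [1, 2, 3, 5, 10, 15, 30]
  force_grid: []
  sampling_rate_hz: 1000.0

simulation:
  n_recordings: 50
  n_domains_max: 9       # (Ubi)_9 polyprotein
  pickup_min: 5
  step_size_nm: 20.0
  noise_sd_nm: 1.0
  render_traces: false   # set true to also write trace TSVs

analysis:
  min_steps_initial: 5
  extension_tol_frac: 0.10
  n_boot: 500

fit:
  n_starts: 8

scan:
  sequence: FAGKQLEDGRT
  offset: 45
  seq_id: ubiquitin_45_55
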