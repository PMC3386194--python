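# Demo run: three chromosomal regions spanning the measured rate range,
# one competition, one growth-curve pair, the protein-burden prediction,
# and deterministic + stochastic take-over at the highest measured (u, s).
seed: 42
regions:
  - name: ter_hotspot
    mu_true: 2.2e-8
    deletable_left_kbp: 8.0
    deletable_right_kbp: 8.0
  - name: mid_chromosome
    mu_true: 5.0e-9
    deletable_left_kbp: 6.0
    deletable_right_kbp: 6.0
  - name: ori_proximal
    mu_true: 5.0e-10
    deletable_left_kbp: 4.0
    deletable_right_kbp: 4.0
fluctuation:
  n_cultures: 9
  N0: 1.0e+6
  Nt: 1.0e+9
  plating_fraction: 0.9
  min_deletion_kbp: 2.0
junctions:
  n_events: 30
  genome_length_bp: 20000
  max_scan: 50
competition:
  s_true: 0.05
  n_cycles: 5
  events_per_timepoint: 100000
growth:
  growth_rate_true: 1.2
  carrying_capacity: 1.5
  noise_sd: 0.005
  relative_rate_true: 1.05
burden:
  r0: 1.0e+9
  genes:
    - [fliC, 495, 20000]
    - [fliD, 466, 2000]
    - [motA, 295, 1000]
fixation:
  u: 2.2e-8
  s: 0.054
  N: 1.0e+9
  target_frequency: 0.5
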