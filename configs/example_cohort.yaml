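# A Lewy-body-like cohort of 10 subjects: slowed dominant rhythm,
# theta-heavy spectrum, weak posterior-hub coupling.
group_label: dlb-example
n_subjects: 10
seed: 42
between_subject_jitter:
  dominant_freq: 1.0
  band_fractions: 0.05
  coupling_strength: 0.10
subject_template:
  dominant_freq: 6.9
  band_fractions:
    delta: 0.41
    theta: 0.34
    alpha1: 0.07
    alpha2: 0.04
    beta: 0.06
    gamma: 0.08
  coupling:                 # [source, target, phase lag (rad), strength]
    - [20, 17, 0.4, 0.45]   # Pz -> O1
    - [20, 16, 0.7, 0.45]   # Pz -> O2
    - [20, 15, 1.0, 0.45]   # Pz -> P3
    - [20, 14, 1.3, 0.45]   # Pz -> P4
  noise_sd: 1.5
  signal_rms: 15.0
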