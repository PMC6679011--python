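bands:
- hi: 1.37
  label: nucleolus
  lo: 1.356
fcs:
  components:
  - D: 25.0
    fraction: 1.0
  dt: 2.0e-06
  enabled: true
  mean_particles_in_volume: 2.0
  n_reps: 3
  rep_duration: 0.2
  s: 5.0
  w: 0.2
min_diameter: 2.0
phantom_noise_sd: 0.0
seed: 0
timelapse:
  cytoplasm_ri:
  - 1.348
  - 1.354
  enabled: true
  interval_min: 40.0
  nucleolus_ri:
  - 1.364
  - 1.376
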