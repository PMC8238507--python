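bands:
  alpha:
  - 8
  - 12
  fast_gamma:
  - 36
  - 66
  slow_gamma:
  - 20
  - 34
baseline_window:
- -0.5
- 0.0
bf_prior_scale: 1.0
eye:
  analysis_window:
  - -0.5
  - 0.75
  fixation_window: 5.0
  lam: 6.0
  merge_gap: 0.02
  min_duration: 0.01
limit_controls: null
microsaccade_filter: none
n_boot: 10000
orientations:
- 0
- 45
- 90
- 135
pool_cases: true
rejection:
  analysis_window:
  - -0.5
  - 0.75
  electrode_bad_repeat_frac: 0.3
  psd_k: 6.0
  repeat_bad_electrode_frac: 0.1
  slope_band:
  - 56.0
  - 84.0
  waveform_k: 6.0
seed: 0
slope_refine: true
spatial_frequencies:
- 2
- 4
ssvep_freq: 32.0
stimulus_window:
- 0.25
- 0.75
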