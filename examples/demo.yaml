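# 20-patient demonstration study: completes in well under a minute.
seed: 3
out_dir: pwavekit_out
n_group0: 14
n_group1: 6
fs: 500.0
record_duration_s: 60.0
noise:
  baseline_wander_mv: 0.05
  powerline_mv: 0.01
  white_sd_mv: 0.01
filter:
  lowpass_hz: 40.0
  highpass_hz: 0.5
  smoothing_window_ms: 20.0
scheme: A
svm:
  points_per_decade: 2
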