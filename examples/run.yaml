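# Full pipeline configuration. Every analysis parameter is explicit.
out_dir: runs/demo
seed: 42

# feature sets to analyze separately (each gets its own learning curve/knee)
feature_sets: [full, envelope]

# synthetic dataset
n_trials: 70            # stimuli; 10 become the repeated test set
channel_count: 32
sampling_rate: 128.0    # Hz
mean_duration: 2.0      # s per trial
snr_db: -10.0
noise_spectrum: pink
design:
  repeated-test: {n_test_stimuli: 10, n_repeats: 10}

# ridge regression
alpha_min_log10: 2.0    # grid 1e2 .. 1e8
alpha_max_log10: 8.0
n_alphas: 15
n_folds: 5
delay_max: 0.6          # s (0-600 ms receptive field window)

# sufficiency analysis
start_size: 10          # trials
step: 2
n_boot: 10
boundary_margin: 0.05
stability_threshold: 0.9
make_plots: true
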