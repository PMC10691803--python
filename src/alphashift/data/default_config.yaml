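# Default pipeline configuration (annotated).
# Any field may be omitted; omitted fields take these defaults.

cohort:
  n_subjects: 20
  master_seed: 0
  # per-subject draws: [mean, sd]
  mean_offset: [-0.3, 0.25]      # oscillatory cycle mean r (dimensionless)
  depth: [-0.5, 0.15]            # target-trial amplitude modulation depth
  peak_latency_s: [0.5, 0.08]    # latency of deepest attenuation (s)
  alpha_freq_hz: [10.0, 0.8]     # individual alpha peak frequency (Hz)
  noise_exponent: [1.0, 0.1]     # chi of the 1/f^chi background
  noise_level_uv: [2.0, 0.3]     # per-sensor broadband noise SD (uV)
  coupling_latency_attention: 0.8   # latent trait loading on trough latency
  coupling_amplitude_memory: 0.8    # latent trait loading on ER amplitude
  age_range: [60.0, 82.0]
  # session geometry (study protocol)
  fs: 1000.0                     # sampling rate (Hz)
  rest_duration_s: 600.0         # eyes-closed rest (s)
  n_stimuli: 600                 # oddball stimuli at fixed ISI
  isi_s: 1.5
  standard_depth_fraction: 0.2   # standard-trial modulation vs target
  include_nuisance: true         # occipital alpha + central mu sources

# filtering
alpha_band_halfwidth_hz: 2.0     # band-pass: alpha peak +- this (Hz)
alpha_filter_order: 4            # zero-phase Butterworth order (alpha band)
lowpass_hz: 3.0                  # ER / baseline-shift low-pass (Hz)
lowpass_order: 8

# analysis windows, seconds relative to stimulus onset
epoch_window_s: [-0.4, 1.3]
baseline_window_s: [-0.2, -0.05]
train_window_s: [0.3, 0.7]       # LDA / CSP feature window
peak_window_s: [0.2, 1.0]        # P300 peak search
post_window_s: [0.2, 1.0]        # envelope trough search

# statistics
n_permutations: 10000            # cluster permutation count
cluster_p_threshold: 1.0e-4      # cluster-forming threshold
bonferroni_base_p: 1.0e-4        # divided by sensor count for masks
n_bsi_bins: 20                   # envelope bins for the baseline-shift index
n_subject_bins: 5                # subject quantile bins for contrasts
n_boot: 2000                     # mediation bootstrap resamples

seed: 0
peak_sensor: Pz
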