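# alphashift

Can a slow evoked response (ER) like the P300 be generated by nothing more
than stimulus-locked *amplitude modulation* of ongoing alpha oscillations?
If an oscillation has a non-zero cycle mean, its amplitude envelope drags a
low-frequency "baseline shift" along with it:

```
y(t) = A(t)·[cos(2πft + θ) + r] = A(t)·cos(2πft + θ) + A(t)·r
```

When a target stimulus attenuates the alpha amplitude `A(t)` trial after
trial, the trial-averaged low-passed signal contains `A(t)·r` — an ER whose
polarity is set by the sign of the oscillatory mean `r` times the direction
of the modulation (attenuated negative-mean alpha ⇒ positive P300-like
deflection).

`alphashift` is a complete, tested pipeline for probing this baseline-shift
mechanism in oddball EEG, aimed at researchers who study evoked responses
and oscillations at the sensor level:

* a generative simulator of non-zero-mean alpha populations and whole
  oddball cohorts (31-channel 10–20 montage, pseudo-randomised stimulus
  sequences, 1/f background, cognitive scores coupled to the latent
  response parameters);
* per-subject preprocessing: epoching with baseline correction, zero-phase
  Butterworth filtering, evoked responses, Hilbert amplitude envelopes with
  evoked-component subtraction, individual alpha peak detection;
* the **baseline-shift index** (BSI): the Pearson correlation of 20
  equal-count envelope-amplitude bins of resting alpha with the bin means
  of the 3 Hz low-passed signal — a resting-state proxy for the sign of `r`;
* subject-pooled spatial filters (shrinkage LDA for the ER contrast, CSP
  for the alpha contrast) with activation patterns `a = Cw/(wᵀCw)`;
* group statistics: normalized envelope change `(A_post−A_pre)/A_pre·100 %`,
  equal-count subject binning, spatio-temporal cluster-based permutation
  tests (mass statistic, max-cluster null), time-course correlations with
  Bonferroni masks, contrast topographies;
* age-adjusted associations of ER/envelope parameters with composite
  cognitive scores, and bootstrap mediation (proportion of the ER–cognition
  association mediated by the alpha parameters).

## Worked example

```python
from alphashift import (SubjectParams, simulate_subject, broadband_filter,
                        detect_alpha_peak, compute_bsi, epoch_and_baseline,
                        compute_er, compute_envelope, average_envelope,
                        find_peak, summarize_envelope, default_montage)

montage = default_montage()
params = SubjectParams(mean_offset=-0.5, depth=-0.5, fs=250.0,
                       rest_duration_s=300.0, n_stimuli=300)
rest, task, truth = simulate_subject(params, montage, seed=42)

rest = broadband_filter(rest)                    # 0.1-45 Hz
peaks = detect_alpha_peak(rest)                  # individual alpha peaks
bsi = compute_bsi(rest, peaks)

epochs = epoch_and_baseline(task)                # -0.4..1.3 s trials
er = compute_er(epochs, "target", lowpass_hz=3.0)
peak = find_peak(er, "Pz")
env_mean, _ = average_envelope(compute_envelope(epochs, peaks), "target")
summary = summarize_envelope(env_mean[montage.index("Pz")],
                             epochs.fs, epochs.t_start_s)
```

which prints, for this subject (alpha with cycle mean `r = −0.5`, 50 %
target-trial attenuation, realistic 1/f noise):

```
alpha peak at Pz:      10.0 Hz
BSI at Pz:             -0.92   (true r = -0.5)
P300 peak:             1.40 uV at 572 ms
alpha envelope change: -51 %  (trough at 548 ms)
```

The resting-state BSI recovers the sign (and grades with the magnitude) of
the oscillatory mean; the task data show the mechanism's signature pair: a
positive parietal ER peaking where the alpha envelope is deepest.

## Command line

```bash
alphashift simulate --config cfg.yaml --out data/ --seed 1   # cohort to disk
alphashift preprocess --data data/                           # cache derived
alphashift bsi --data data/                                  # per-sensor BSI
alphashift spatial --data data/                              # LDA + CSP
alphashift bin-test --data data/                             # depth-bin cluster test
alphashift bsi-test --data data/                             # BSI-bin cluster test
alphashift associate --data data/                            # cognition links
alphashift report --out report/ --seed 1                     # full 4-prediction suite
```

An annotated default configuration ships at
`src/alphashift/data/default_config.yaml`.  Recordings are stored as a flat
`.npy` array + JSON sidecar + tab-separated events (`onset_s`, `code`);
montages as tab-separated `label x y z`.

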