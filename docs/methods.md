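# Methods

## The baseline-shift mechanism

`alphashift` tests whether a slow evoked response (ER) such as the P300 can
be generated by stimulus-locked amplitude modulation of ongoing
oscillations whose cycle mean is not zero.  The signal model is

    y(t) = A(t) · [cos(2πft + θ) + r]
         = A(t) · cos(2πft + θ)  +  A(t) · r

with carrier frequency `f` (alpha, 8–12 Hz), phase `θ`, amplitude
modulation `A(t)` and dimensionless cycle-mean offset `r`.  The term
`A(t)·r` is a *baseline shift* riding along with the oscillation in the
0–3 Hz range.  If a stimulus systematically attenuates `A(t)` — the
classic post-stimulus alpha desynchronisation — the trial average of the
low-passed signal contains the attenuation profile scaled by `r`.  Three
consequences follow, and each is a testable prediction:

1. the ER and the alpha amplitude envelope share their time course
   (inversely, for `r < 0` with attenuation);
2. they share their scalp topography;
3. the ER polarity is fixed by `sign(r) × sign(modulation)` — attenuated
   negative-mean oscillations give a *positive* ER.

A fourth, indirect prediction is that external correlates (cognitive
scores) relate to ER parameters and envelope parameters in the same
direction, with the envelope parameters mediating part of the ER–score
association.

For a *population* of `n_units` oscillators sharing `A(t)` and `r` but
with individual phases, the mean carrier is `C·cos(2πft + φ)` where
`C·e^{iφ}` is the circular resultant of the phases (the simulator uses
this identity, which makes the cost independent of `n_units`).  The key
asymmetry: the carrier amplitude seen at the scalp scales with the phase
coupling `sync`, but the baseline shift `A(t)·r` is common-mode and does
not.  Scalp alpha power therefore cannot be converted into an expected ER
size without knowing the synchronisation — which is why the package never
attempts to state "x % of the ER is oscillatory".

## Synthetic cohort

The generator emulates a large elderly oddball cohort recorded with 31
sensors (10–20 montage, common-average reference):

* **Sessions.** Eyes-closed rest (study protocol: 10 min at 1000 Hz; the
  first 10 min are what the baseline-shift index uses) and an auditory
  oddball session of 600 stimuli at a fixed 1.5 s ISI — 76 % standards,
  12 % targets, 12 % novelty sounds, pseudo-randomised with ≥2 standards
  between targets and ≤9 standards in a row.  The sequence sampler orders
  the rare stimuli at random, pre-allocates the minimum standards after
  each non-final target and drops the remaining standards into gaps with
  capacity 9; a bounded rejection loop over plain shuffles runs first,
  but valid 600-item shuffles are so rare (expected ≈9 over-long standard
  runs per draw) that the constructive path is the workhorse.
* **Sources.** A task-modulated alpha source centred on Pz (the ER
  generator, with subject-specific `r`), an unmodulated occipital alpha
  source (`0.8·r`, higher amplitude — the eyes-closed occipital rhythm
  that masks raw target topographies) and a zero-mean central mu source.
  Each projects through a synthetic lead field of Gaussian bumps
  (σ = 5 cm) over the montage positions.  This is deliberately not a
  volume-conduction model; it is smooth and localised, which is all the
  sensor-level claims need, but it spreads less than real conduction, so
  topography rank-overlap statistics are weaker than in real data.
* **Dynamics.** Amplitudes fluctuate slowly (low-passed Gaussian,
  SD 15–30 % of the base amplitude, characteristic time ≈ 5 s); the
  carrier phase diffuses via low-passed instantaneous-frequency drift
  (SD 0.4 Hz).  Without phase diffusion a 10 Hz carrier would be
  phase-locked to the 1.5 s ISI (an exact multiple of its period) and
  would survive trial averaging as a spurious ER.
* **Task modulation.** Each stimulus multiplies the task source's
  amplitude by a raised-cosine dip starting 200 ms post-stimulus,
  reaching `1 + depth` at the subject's trough latency (default 500 ms)
  and recovering by 1200 ms — matching the observed co-localisation of
  the P300 peak and the deepest alpha attenuation in the 400–700 ms
  window.  Targets get the full subject `depth` (multiplicative
  trial-to-trial jitter, SD 0.2); standards and novelty sounds get 20 %
  of it (configurable to 0).
* **Noise.** Per-sensor 1/f^χ Gaussian noise (default χ = 1, SD 2 µV)
  plus a shared broadband 1/f source at half that level.  The synthetic
  1/f spectrum keeps rising below 0.1 Hz, which real recordings would
  remove with the standard 0.1–45 Hz acquisition band-pass; the pipeline
  applies exactly that band-pass before resting-state analyses.
* **Defaults.** Alpha base amplitude 5 µV (10 µV peak-to-peak),
  `r ~ N(−0.3, 0.25)` (predominantly negative mean, as the empirical BSI
  distributions suggest), `depth ~ N(−0.5, 0.15)`, trough latency
  `N(0.5 s, 0.08 s)`, alpha peak `N(10, 0.8)` Hz.
* **Cognition.** Attention and executive latent traits load negatively on
  the true trough latency, memory loads positively on the true ER
  amplitude `|r·depth|·A`; all include an age slope (−0.03 SD/yr) and
  unit Gaussian noise.  Raw scores are log-normal times-to-complete
  (TMT-A/B, Stroop neutral/incongruent — *inverted* before z-scoring) and
  clipped recall fractions; ~1 % of entries are dropped to NaN so the
  imputation path is exercised.

What the generator does **not** emulate: volume conduction and sensor
covariance structure of a real head, eye/muscle artifacts, non-stationary
vigilance drifts, any non-BSM contribution to the P300 (additive or
phase-reset components), and novelty-specific responses.  Passing tests
therefore show that the *machinery* recovers a known mechanism under
realistic SNR — not that real P300s are fully explained by it.

## Analysis pipeline

Per subject: 0.1–45 Hz band-pass of the rest recording; per-sensor
individual alpha peak from Welch spectra (2 s segments, 50 % overlap,
local maximum ≥0.15 decades above a fitted log-log 1/f line in 8–12 Hz,
fallback 10 Hz with a flag); epochs −0.4…1.3 s, baseline −0.2…−0.05 s;
ER = trial average, low-passed at 3 Hz (order-8 zero-phase Butterworth);
envelope = per-trial magnitude of the analytic signal after subtracting
the condition-matched broadband ER and band-passing ±2 Hz around the
alpha peak (order-4 zero-phase Butterworth).  The baseline-shift index
(BSI) correlates 20 equal-count envelope-amplitude bins of the resting
envelope with the bin means of the 3 Hz low-passed signal (Pearson over
the 20 paired means; first/last second excluded).

Equal-count bins were chosen over equal-width because they make every bin
mean equally reliable; the low-frequency bin statistic is the *signed*
mean, since baseline shifts are signed.

Group level: per-sensor Pearson correlation of grand-average ER and
envelope time courses (Bonferroni mask at 10⁻⁴/31); target-vs-standard
contrast topographies (ER difference and envelope ratio in ±50 ms around
the P300 peak; peak search 0.2–1.0 s at Pz, fallback 500 ms) compared by
Spearman rank correlation; subjects binned into 5 equal-count bins by
normalized envelope change `(A_post − A_pre)/A_pre · 100 %` or by BSI,
with the extreme bins contrasted by a spatio-temporal cluster-based
permutation test (pooled-variance t at every sensor×sample;
cluster-forming threshold = two-sided t quantile at p = 10⁻⁴; clusters
connected through Delaunay sensor adjacency — edges capped at 1.5× the
median length — at one sample, or the same sensor at adjacent samples;
mass = summed t; null = max |mass| over unpaired label permutations;
p = (1+k)/(1+n_perm)).

Spatial filtering pools over subjects: a shrinkage LDA (scikit-learn,
lsqr/Ledoit–Wolf — the analytic shrinkage matters for small synthetic
cohorts, while 31-dim large-cohort data would barely need it) trained on
target vs standard window-averaged (0.3–0.7 s) ER amplitudes, and CSP
from grand-average alpha-band trial covariances in the same window,
solved by whitening the composite covariance and eigendecomposing the
whitened target covariance (stabler than a direct generalised solver;
ridge fallback on rank deficiency).  Filters are reported with their
activation patterns `a = Cw/(wᵀCw)` (filter normalised to unit length, so
the pattern is scale-invariant); the CSP component is selected by
absolute cosine similarity of its pattern to the ER contrast topography,
ties broken by eigenvalue.

Cognition: composites are means of z-scored tests (times-to-complete
inverted as 1/value; missing and implausible values — beyond 3 IQRs —
mean-imputed); marker–score associations are OLS with the marker
standardised and age as covariate; mediation uses the three-regression
decomposition (total: `y ~ x + age`; mediator path: `m ~ x`; full:
`y ~ x + m + age`) with the proportion mediated = indirect/total and
percentile-bootstrap CIs (case resampling).  The bootstrap was chosen
over quasi-Bayesian simulation as the simplest assumption-light
uncertainty estimate for the same point decomposition; when total and
indirect effects disagree in sign the "proportion" is flagged rather than
interpreted.

## Numerical choices

* **Filter edges.** Zero-phase filtering of a 1.7 s epoch with a ±2 Hz
  order-4 band-pass is transient-dominated under any reflection padding
  (8–15 % ringing 200 ms into the epoch, measured on a pure tone),
  because reflection breaks the oscillation's phase at the boundary.
  Short signals are therefore extended by Yule–Walker linear prediction
  (AR order 30, three settling lengths on each side) before `filtfilt`,
  which continues the oscillation coherently (≈0.5 % edge error).  Long
  signals keep reflection padding; `compute_er`'s low-pass keeps it
  explicitly so averaging+filtering stays exactly linear in the data.
  The first/last 200 ms of every envelope epoch remain flagged as
  edge-unreliable; statistics windows avoid them.
* **Ties.** The envelope trough is the earliest argmin in the 0.2–1.0 s
  window; quantile bins break ties by stable input order (logged);
  CSP component selection breaks similarity ties by larger eigenvalue.
* **Degenerate inputs.** Constant traces yield undefined correlations and
  are masked and logged; a constant test column z-scores to 0; a zero
  reference topography, zero-variance mediator and non-positive baseline
  amplitude raise errors.
* **Permutation p-values** use the (1+k)/(1+n) estimator; validity was
  checked empirically (see below).
* **Determinism.** Every stochastic step draws from
  `numpy.random.Generator` seeded from a master seed via
  `SeedSequence.spawn`; per-subject substreams make any single subject
  reproducible in isolation.

## Test and acceptance problem sizes

The verification suite scales the study protocol down to desk size; all
sizes are package choices recorded here:

* mechanism triad: single subjects, 600 stimuli at 250 Hz, exemplar
  `r = −0.7`, `depth = −0.5`; the r = 0 noise floor from 8 null subjects;
* linearity in `r`: 100-trial averages of an incoherent population
  (uniform per-trial phases), 6 offsets in ±0.8;
* synchronisation sweep: 500 units, 80 trials per `sync ∈ {0, .25, .5, 1}`;
* BSI: full 10-min rests; 100 subjects at `|r| = 0.5` for sign recovery,
  8 × 4 offsets (5-min rests) for monotonicity;
* cluster-test calibration: 1000 null data sets on a 4-sensor × 12-sample
  grid, 10 + 10 subjects, 500 permutations each, cluster-forming p = 0.05
  (at the production threshold of 10⁻⁴ the null max-mass distribution
  degenerates to an atom at zero and the empirical rate is trivially
  conservative; calibration is only informative where the null is
  non-degenerate);
* depth binning: 500 subjects varying only in depth (SD 0.15), 300
  stimuli each — 36 targets halve the per-subject ER floor relative to a
  150-stimulus session and keep the quintile dose-response resolvable
  (the study itself has 72 targets per subject);
* BSI→polarity: 200 subjects, `r ~ N(0, 0.45)`, 5-min rests;
* mediation: n = 2000 with 2000 bootstrap resamples.

`scripts/acceptance.py` re-runs the full four-prediction suite on a
40-subject cohort (300 s rests, 150 stimuli, 250 Hz) plus the mechanism
measurements above at the same sizes.  At 40 subjects the binned cluster
contrast of a fully heterogeneous cohort has no power at the production
threshold, so the script measures the binning dose-response on the
150-subject depth-controlled cohort instead.

## Known limitations

* The synthetic lead field spreads less than real volume conduction, so
  cross-sensor rank statistics (topography Spearman) are attenuated
  relative to real-data values even though their sign is reproduced.
* The simulated P300 is *entirely* baseline-shift generated; the package
  cannot, by construction, say anything about additive or phase-reset
  contributions to real ERs.
* BSI reliability depends strongly on rest duration; at 60 s the
  estimator is near chance under realistic noise, which mirrors the
  field's practice of using ≥5–10 min of rest.
* The default cluster permutation test assumes exchangeable subjects
  between the contrasted bins (unpaired design, which is what disjoint
  quantile bins are); a sign-flip variant for paired difference maps is
  provided but unused by the default pipeline.
* Event sequences constrain only standards-between-targets and standard
  run lengths; real paradigms may balance novelty placement too.
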