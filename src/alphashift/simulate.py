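"""Generative model of non-zero-mean alpha oscillations and oddball cohorts.

The core signal model is an amplitude-modulated oscillation with a constant
offset added *inside* the modulation::

    y(t) = A(t) * [cos(2*pi*f*t + theta) + r]
         = A(t) * cos(2*pi*f*t + theta)  +  A(t) * r

``r`` is the (dimensionless) non-zero mean of the oscillatory cycle and
``A(t) * r`` is the *baseline shift* that accompanies the oscillation.  When
a stimulus systematically attenuates ``A(t)`` trial after trial, the
trial-averaged low-frequency signal contains the attenuation profile scaled
by ``r``: an evoked response generated purely by amplitude modulation.  Its
polarity is the product of the sign of ``r`` and the direction of the
modulation — negative-mean oscillations that are attenuated produce a
positive deflection.

On top of this single-oscillator model the module builds:

* populations of oscillators with partial phase coupling (``sync``), to show
  that scalp envelope amplitude depends on synchronisation while the
  baseline shift does not;
* pseudo-randomised auditory oddball stimulus sequences;
* whole "subjects": multi-sensor recordings (rest + task) obtained by mixing
  a parietal task-modulated alpha source, nuisance occipital alpha and
  central mu sources through a synthetic Gaussian-bump lead field, plus
  1/f background noise, under a common-average reference;
* whole cohorts with per-subject parameter draws and cognitive scores
  coupled to the latent evoked-response parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filters import zero_phase_butterworth
from .montage import Montage, default_montage, gaussian_mixing

logger = logging.getLogger(__name__)

__all__ = [
    "OscillatorSpec", "ModulationProfile", "CohortSpec", "SubjectParams",
    "Recording", "Cohort", "AliasingError", "SequenceConstraintError",
    "evaluate_modulation", "simulate_oscillation",
    "simulate_population_sync_sweep", "generate_oddball_events",
    "simulate_subject", "simulate_cohort", "oneoverf_noise",
]

STANDARD, TARGET, NOVELTY = "standard", "target", "novelty"
CODES = (STANDARD, TARGET, NOVELTY)


class AliasingError(ValueError):
    """Sampling rate below the Nyquist rate of the carrier."""


class SequenceConstraintError(RuntimeError):
    """Oddball sequence constraints cannot be satisfied for the requested counts."""


class InvalidProfileError(ValueError):
    """Modulation profile evaluates to a negative amplitude."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OscillatorSpec:
    """A population of oscillators sharing carrier frequency and offset.

    Parameters
    ----------
    carrier_freq_hz : float
        Carrier frequency ``f`` in Hz; must be positive.
    phase_rad : float
        Common phase ``theta`` of the coupled fraction of the population.
    mean_offset : float
        Non-zero mean ``r`` as a fraction of the unit carrier.
    base_amplitude : float
        Amplitude scale in microvolts applied on top of the modulation.
    n_units : int
        Number of population members.
    sync : float
        Fraction of members phase-locked to ``phase_rad``; the remainder
        draw independent uniform phases.  1 means a fully coherent source.
    """

    carrier_freq_hz: float
    phase_rad: float = 0.0
    mean_offset: float = 0.0
    base_amplitude: float = 1.0
    n_units: int = 1
    sync: float = 1.0

    def __post_init__(self):
        if self.carrier_freq_hz <= 0:
            raise ValueError("carrier_freq_hz must be > 0")
        if not 0.0 <= self.sync <= 1.0:
            raise ValueError("sync must be in [0, 1]")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


@dataclass
class ModulationProfile:
    """Event-locked amplitude modulation ``A(t)``.

    ``A(t)`` equals ``baseline_level`` outside ``[onset_s, onset_s +
    duration_s]`` and follows a smooth dip (or hump, for positive ``depth``)
    inside it, reaching ``baseline_level * (1 + depth)`` at
    ``peak_latency_s``.  The default raised-cosine shape rises from the
    onset to the trough and recovers by ``onset_s + duration_s``; the two
    half-windows may be asymmetric.

    Defaults (onset 0.2 s, trough 0.5 s, recovery by 1.2 s) describe the
    canonical post-stimulus alpha attenuation time course, whose trough
    co-occurs with the 400-700 ms window where the P300 is largest.
    """

    baseline_level: float = 1.0
    depth: float = 0.0
    onset_s: float = 0.2
    peak_latency_s: float = 0.5
    duration_s: float = 1.0
    shape: str = "raised_cosine"

    def __post_init__(self):
        if self.depth < -1.0:
            raise InvalidProfileError("depth < -1 would drive the amplitude negative")
        if self.baseline_level < 0:
            raise InvalidProfileError("baseline_level must be >= 0")
        if not self.onset_s <= self.peak_latency_s <= self.onset_s + self.duration_s:
            raise InvalidProfileError("peak_latency_s must lie inside the event window")
        if self.shape not in ("raised_cosine",):
            raise InvalidProfileError(f"unknown modulation shape {self.shape!r}")


@dataclass
class SubjectParams:
    """Latent generative parameters of one simulated participant."""

    mean_offset: float = -0.3          # r of the parietal task alpha source
    depth: float = -0.5                # target-trial modulation depth
    peak_latency_s: float = 0.5        # latency of deepest attenuation
    alpha_freq_hz: float = 10.0
    base_amplitude_uv: float = 5.0     # 10 uV peak-to-peak pre-stimulus
    noise_exponent: float = 1.0        # chi of the 1/f^chi background
    noise_level_uv: float = 2.0        # per-sensor broadband noise SD
    standard_depth_fraction: float = 0.2
    trial_jitter_sd: float = 0.2       # multiplicative jitter of per-trial depth
    include_nuisance: bool = True
    fs: float = 1000.0
    rest_duration_s: float = 600.0
    n_stimuli: int = 600
    isi_s: float = 1.5
    subject_id: int = 0


@dataclass
class CohortSpec:
    """Population-level distributions for a simulated oddball cohort.

    Distribution fields are ``(mean, sd)`` of per-subject Gaussian draws.
    Defaults reproduce the study conditions being emulated: a 31-channel
    common-average montage at 1000 Hz, 10 min eyes-closed rest, a 15-min
    auditory oddball with 600 stimuli (76/12/12 % standard/target/novelty)
    at an invariant 1.5 s ISI, predominantly negative-mean parietal alpha
    with roughly half-amplitude attenuation after targets, and cognitive
    scores coupled to the latent response latency (attention, executive)
    and amplitude (memory).
    """

    n_subjects: int = 20
    mean_offset: tuple = (-0.3, 0.25)
    depth: tuple = (-0.5, 0.15)
    peak_latency_s: tuple = (0.5, 0.08)
    alpha_freq_hz: tuple = (10.0, 0.8)
    noise_exponent: tuple = (1.0, 0.1)
    noise_level_uv: tuple = (2.0, 0.3)
    coupling_latency_attention: float = 0.8
    coupling_amplitude_memory: float = 0.8
    age_range: tuple = (60.0, 82.0)
    master_seed: int = 0
    # recording geometry / session sizes (shared by all subjects)
    fs: float = 1000.0
    rest_duration_s: float = 600.0
    n_stimuli: int = 600
    isi_s: float = 1.5
    standard_depth_fraction: float = 0.2
    include_nuisance: bool = True

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("mean_offset", "depth", "peak_latency_s", "alpha_freq_hz",
                     "noise_exponent", "noise_level_uv"):
            m, s = getattr(self, name)
            if s < 0:
                raise ValueError(f"{name} sd must be >= 0")


@dataclass
class Recording:
    """A continuous multichannel recording in microvolts.

    ``events`` is a list of ``(onset_sample, code)`` with codes in
    ``{"standard", "target", "novelty"}``.
    """

    data: np.ndarray            # (n_sensors, n_samples)
    fs: float
    sensor_labels: list[str]
    events: list = field(default_factory=list)
    reference_tag: str = "common_average"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.sensor_labels):
            raise ValueError("data must be (n_sensors, n_samples)")
        n = self.data.shape[1]
        for onset, code in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside [0, {n})")
            if code not in CODES:
                raise ValueError(f"unknown event code {code!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.fs


# ---------------------------------------------------------------------------
# amplitude modulation and the oscillator
# ---------------------------------------------------------------------------

def evaluate_modulation(profile: ModulationProfile, t) -> np.ndarray:
    """Evaluate ``A(t)`` of a modulation profile on a time grid.

    ``t`` must be strictly increasing.  The result is ``baseline_level``
    outside the event window and non-negative everywhere; a profile that
    would evaluate negative raises :class:`InvalidProfileError`.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t must be a strictly increasing 1-D grid")
    a = np.full(t.shape, float(profile.baseline_level))
    w = unit_dip(profile, t)
    a *= 1.0 + profile.depth * w
    if np.any(a < -1e-12):
        raise InvalidProfileError("profile evaluates to a negative amplitude")
    return np.clip(a, 0.0, None)


def unit_dip(profile: ModulationProfile, t) -> np.ndarray:
    """Unit-amplitude window of the modulation: 0 outside, 1 at the trough."""
    t = np.asarray(t, dtype=float)
    t0, tp = profile.onset_s, profile.peak_latency_s
    t1 = profile.onset_s + profile.duration_s
    w = np.zeros_like(t)
    if tp > t0:
        rise = (t >= t0) & (t < tp)
        w[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - t0) / (tp - t0))
    fall = (t >= tp) & (t <= t1)
    if t1 > tp:
        w[fall] = 0.5 + 0.5 * np.cos(np.pi * (t[fall] - tp) / (t1 - tp))
    else:
        w[fall] = 1.0
    return w


def _population_carrier(spec: OscillatorSpec, rng: np.random.Generator):
    """Resultant (C, phi) of the population phase distribution.

    The population average of ``cos(w t + theta_i)`` equals
    ``C * cos(w t + phi)`` where ``C * exp(i phi)`` is the circular mean of
    ``exp(i theta_i)``.  Collapsing the unit sum onto the resultant is exact
    for units sharing the same ``A(t)`` and makes the cost independent of
    ``n_units``.
    """
    n_sync = int(round(spec.sync * spec.n_units))
    phases = np.full(spec.n_units, spec.phase_rad)
    if spec.n_units - n_sync > 0:
        phases[n_sync:] = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_units - n_sync)
    resultant = np.mean(np.exp(1j * phases))
    return np.abs(resultant), np.angle(resultant)


def simulate_oscillation(spec: OscillatorSpec, profile: ModulationProfile,
                         duration_s: float, fs: float, seed=None) -> np.ndarray:
    """Single-channel trace of a (population of) modulated oscillator(s).

    The population mean of ``A(t) * [cos(2 pi f t + theta_i) + r]`` over
    ``n_units`` members.  Phase coupling follows ``spec.sync``: a fraction
    ``sync`` of units share ``spec.phase_rad`` and the rest draw independent
    uniform phases.  Note that the baseline-shift term ``A(t) * r`` is
    common to every unit and therefore survives averaging unchanged, however
    incoherent the population.

    Raises
    ------
    AliasingError
        If ``fs < 2 * carrier_freq_hz``.
    ValueError
        If the trace would span fewer than 10 carrier cycles.
    """
    if fs < 2.0 * spec.carrier_freq_hz:
        raise AliasingError(
            f"fs={fs} Hz cannot represent a {spec.carrier_freq_hz} Hz carrier")
    if duration_s * spec.carrier_freq_hz < 10.0:
        raise ValueError("duration must cover at least 10 carrier cycles")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    a = evaluate_modulation(profile, t) * spec.base_amplitude
    c, phi = _population_carrier(spec, rng)
    carrier = c * np.cos(2.0 * np.pi * spec.carrier_freq_hz * t + phi)
    return a * (carrier + spec.mean_offset)


def simulate_population_sync_sweep(spec: OscillatorSpec, profile: ModulationProfile,
                                   sync_values, seed=None, n_trials: int = 100,
                                   duration_s: float = 3.0, fs: float = 500.0,
                                   lowpass_hz: float = 3.0) -> pd.DataFrame:
    """Measure envelope modulation and baseline shift across coupling levels.

    For each ``sync`` value, ``n_trials`` independent population draws are
    simulated with the same modulation profile.  Two summary measurements
    are taken from the trial set:

    * ``envelope_modulation`` — drop of the trial-averaged alpha-band
      Hilbert envelope from its pre-onset mean to its minimum (uV).  This
      tracks the scalp-visible oscillation amplitude, which grows with
      synchronisation.
    * ``baseline_shift`` — peak absolute deviation of the low-passed
      trial-averaged trace from its pre-onset mean (uV).  This tracks
      ``A(t) * r`` and is insensitive to synchronisation.

    Returns a DataFrame with columns ``sync, envelope_modulation,
    baseline_shift``.
    """
    if spec.n_units < 2:
        raise ValueError("a synchronisation sweep needs n_units >= 2")
    sync_values = np.asarray(list(sync_values), dtype=float)
    if np.any((sync_values < 0) | (sync_values > 1)):
        raise ValueError("sync values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    edge_s = 0.75            # keep clear of the zero-phase filter settling
    interior = (t >= edge_s) & (t <= duration_s - edge_s)
    pre = (t < profile.onset_s) & interior
    if not pre.any():
        raise ValueError("no pre-onset interior samples; lengthen the trace")
    f = spec.carrier_freq_hz
    rows = []
    from .filters import envelope as _env  # local import to avoid cycle at module load
    for sync in sync_values:
        sp = replace(spec, sync=float(sync))
        traces = np.empty((n_trials, t.size))
        for k in range(n_trials):
            traces[k] = simulate_oscillation(sp, profile, duration_s, fs,
                                             seed=rng.integers(2**31))
        mean_trace = traces.mean(axis=0)
        lf = zero_phase_butterworth(mean_trace, fs, "lowpass", lowpass_hz, order=8)
        shift = np.max(np.abs(lf[interior] - lf[pre].mean()))
        band = zero_phase_butterworth(traces, fs, "bandpass",
                                      (f - 2.0, f + 2.0), order=4, axis=-1)
        env = _env(band, axis=-1).mean(axis=0)
        modulation = env[pre].mean() - env[interior].min()
        rows.append((float(sync), float(modulation), float(shift)))
    return pd.DataFrame(rows, columns=["sync", "envelope_modulation", "baseline_shift"])


# ---------------------------------------------------------------------------
# oddball stimulus sequences
# ---------------------------------------------------------------------------

def _sequence_ok(codes, min_between: int, max_run: int) -> bool:
    run = 0
    since_target = None
    for c in codes:
        if c == STANDARD:
            run += 1
            if run > max_run:
                return False
            if since_target is not None:
                since_target += 1
        else:
            run = 0
            if c == TARGET:
                if since_target is not None and since_target < min_between:
                    return False
                since_target = 0
    return True


def generate_oddball_events(n_stimuli: int = 600,
                            proportions=(0.76, 0.12, 0.12),
                            min_standards_between_targets: int = 2,
                            max_standard_run: int = 9,
                            isi_s: float = 1.5,
                            seed=None,
                            max_reject_attempts: int = 100) -> list:
    """Pseudo-randomised oddball sequence with exact per-category counts.

    Counts per category are ``round(n * p)`` (any rounding remainder is
    absorbed by the standards).  Two constraints are enforced: at least
    ``min_standards_between_targets`` standards between consecutive targets
    and at most ``max_standard_run`` standards in succession.  Onsets are
    spaced exactly ``isi_s`` seconds starting at 0.

    A bounded rejection loop over unconstrained shuffles runs first; because
    valid sequences are vanishingly rare among the 600-stimulus shuffles,
    the workhorse is a seeded constructive sampler: rare stimuli (targets
    and novelties) are ordered at random, the minimum standards are
    pre-allocated into the gap after every non-final target, and the
    remaining standards fall uniformly into gaps with free capacity
    (each gap holds at most ``max_standard_run``).

    Returns a list of ``(onset_s, code)`` tuples.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != 3 or abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be three values summing to 1")
    n_tgt = int(round(n_stimuli * proportions[1]))
    n_nov = int(round(n_stimuli * proportions[2]))
    n_std = n_stimuli - n_tgt - n_nov
    if n_std < 0:
        raise SequenceConstraintError("rare-stimulus counts exceed n_stimuli")
    rng = np.random.default_rng(seed)

    codes = np.array([STANDARD] * n_std + [TARGET] * n_tgt + [NOVELTY] * n_nov)
    for _ in range(max_reject_attempts):
        rng.shuffle(codes)
        if _sequence_ok(codes, min_standards_between_targets, max_standard_run):
            break
    else:
        logger.debug("rejection sampling exhausted %d attempts; using the "
                     "constructive sampler", max_reject_attempts)
        codes = _constructive_sequence(
            n_std, n_tgt, n_nov, min_standards_between_targets,
            max_standard_run, rng)
        if not _sequence_ok(codes, min_standards_between_targets, max_standard_run):
            raise SequenceConstraintError("constructive sampler produced an invalid "
                                          "sequence; constraints are infeasible")
    onsets = np.arange(n_stimuli) * isi_s
    return [(float(o), str(c)) for o, c in zip(onsets, codes)]


def _constructive_sequence(n_std, n_tgt, n_nov, min_between, max_run, rng):
    rare = np.array([TARGET] * n_tgt + [NOVELTY] * n_nov)
    rng.shuffle(rare)
    n_gaps = rare.size + 1
    gaps = np.zeros(n_gaps, dtype=int)
    # guarantee spacing: gap immediately after every non-final target
    target_pos = np.flatnonzero(rare == TARGET)
    for pos in target_pos[:-1] if target_pos.size else []:
        gaps[pos + 1] = min_between
    if gaps.sum() > n_std:
        raise SequenceConstraintError(
            f"{n_std} standards cannot give {min_between} between {n_tgt} targets")
    remaining = n_std - gaps.sum()
    capacity = max_run - gaps
    if capacity.sum() < remaining:
        raise SequenceConstraintError(
            f"standards overflow: runs of <= {max_run} cannot absorb {n_std}")
    open_gaps = list(np.flatnonzero(capacity > 0))
    for _ in range(remaining):
        g = open_gaps[rng.integers(len(open_gaps))]
        gaps[g] += 1
        if gaps[g] >= max_run:
            open_gaps.remove(g)
    out = []
    for i in range(rare.size):
        out.extend([STANDARD] * gaps[i])
        out.append(rare[i])
    out.extend([STANDARD] * gaps[-1])
    return np.array(out)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def oneoverf_noise(n_samples: int, fs: float, exponent: float = 1.0,
                   rng=None, n_channels: int = 1) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance.

    Spectral shaping is done in the frequency domain; the DC bin is zeroed
    and each channel is standardised to zero mean and unit standard
    deviation so callers control the level explicitly.
    """
    rng = np.random.default_rng(rng)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    x /= sd
    return x[0] if n_channels == 1 else x


def _slow_fluctuation(n_samples: int, fs: float, rng, cutoff_hz: float = 0.2,
                      sd: float = 0.3) -> np.ndarray:
    """Smooth multiplicative envelope fluctuation around 1 (clipped >= 0.05)."""
    white = rng.standard_normal(n_samples)
    slow = zero_phase_butterworth(white, fs, "lowpass", cutoff_hz, order=2)
    s = slow.std()
    if s > 0:
        slow = slow / s * sd
    return np.clip(1.0 + slow, 0.05, None)


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _source_definitions(params: SubjectParams, montage: Montage):
    """(name, spec, center labels, sigma, task-modulated?) for each source."""
    sources = [
        ("task_alpha",
         OscillatorSpec(params.alpha_freq_hz, mean_offset=params.mean_offset,
                        base_amplitude=params.base_amplitude_uv),
         ["Pz"], 0.05, True),
    ]
    if params.include_nuisance:
        sources.append(
            ("occipital_alpha",
             OscillatorSpec(params.alpha_freq_hz + 0.4,
                            mean_offset=0.8 * params.mean_offset,
                            base_amplitude=1.2 * params.base_amplitude_uv),
             ["O1", "O2"], 0.045, False))
        sources.append(
            ("mu",
             OscillatorSpec(11.0, mean_offset=0.0,
                            base_amplitude=0.6 * params.base_amplitude_uv),
             ["C3", "C4"], 0.04, False))
    return sources


def _diffusing_phase(f0, n_samples, fs, rng, drift_sd_hz=0.4):
    """Carrier phase with slow instantaneous-frequency drift.

    Ongoing alpha is not a rigid sinusoid: its phase decoheres over a few
    seconds.  Without this drift, a carrier whose period divides the ISI
    would be artificially phase-locked to every stimulus and survive trial
    averaging.
    """
    drift = zero_phase_butterworth(rng.standard_normal(n_samples), fs,
                                   "lowpass", 1.0, order=2)
    s = drift.std()
    if s > 0:
        drift = drift / s * drift_sd_hz
    f_inst = f0 + drift
    return rng.uniform(0.0, 2.0 * np.pi) + 2.0 * np.pi * np.cumsum(f_inst) / fs


def _render_sources(params, montage, n_samples, fs, rng, modulation=None,
                    return_truth=False):
    """Mix oscillatory sources + 1/f noise into a common-average recording."""
    sources = _source_definitions(params, montage)
    data = np.zeros((len(montage), n_samples))
    truth = {}
    for name, spec, centers, sigma, modulated in sources:
        mix = gaussian_mixing(montage, centers, sigma)
        task_modulated = modulated and modulation is not None
        amp = spec.base_amplitude * _slow_fluctuation(
            n_samples, fs, rng, sd=0.15 if task_modulated else 0.3)
        if task_modulated:
            amp = amp * modulation
        phase = _diffusing_phase(spec.carrier_freq_hz, n_samples, fs, rng)
        src = amp * (np.cos(phase) + spec.mean_offset)
        data += np.outer(mix, src)
        if return_truth:
            truth[name] = {"mixing": mix, "amplitude": amp,
                           "mean_offset": spec.mean_offset,
                           "carrier_freq_hz": spec.carrier_freq_hz}
    if params.noise_level_uv > 0:
        noise = oneoverf_noise(n_samples, fs, params.noise_exponent,
                               rng, n_channels=len(montage))
        shared = oneoverf_noise(n_samples, fs, params.noise_exponent, rng)
        data += params.noise_level_uv * noise
        data += 0.5 * params.noise_level_uv * shared[np.newaxis, :]
    data -= data.mean(axis=0, keepdims=True)  # common-average reference
    return (data, truth) if return_truth else (data, None)


def simulate_subject(params: SubjectParams, montage: Montage | None = None,
                     seed=None):
    """Simulate one participant: resting-state and oddball-task recordings.

    The task recording applies the subject's modulation profile to the
    parietal alpha source at every stimulus: full ``depth`` (with
    multiplicative trial-to-trial jitter) after targets, and
    ``standard_depth_fraction * depth`` after standards and novelty sounds.
    Nuisance sources are never task-modulated.

    Returns
    -------
    rest : Recording
    task : Recording
    truth : dict
        Generative ground truth: the subject parameters, per-source mixing
        columns and amplitude traces (``A(t)``), and per-trial effective
        depths — everything a recovery test needs.
    """
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    fs = params.fs

    # --- rest -------------------------------------------------------------
    n_rest = int(round(params.rest_duration_s * fs))
    rest_rng = np.random.default_rng(rng.integers(2**31))
    rest_data, rest_truth = _render_sources(params, montage, n_rest, fs,
                                            rest_rng, return_truth=True)
    rest = Recording(rest_data, fs, list(montage.labels), [], "common_average")

    # --- task -------------------------------------------------------------
    task_rng = np.random.default_rng(rng.integers(2**31))
    events = generate_oddball_events(params.n_stimuli, isi_s=params.isi_s,
                                     seed=task_rng.integers(2**31))
    lead_in, lead_out = 2.0, 2.0
    n_task = int(round((lead_in + params.n_stimuli * params.isi_s + lead_out) * fs))
    modulation = np.ones(n_task)
    trial_depths = []
    subj_profile = ModulationProfile(onset_s=0.2,
                                     peak_latency_s=params.peak_latency_s,
                                     duration_s=1.0)
    base_window = unit_dip(subj_profile, np.arange(0, 1.3, 1.0 / fs))
    w_len = base_window.size
    for onset_s, code in events:
        onset = int(round((lead_in + onset_s) * fs))
        jitter = max(0.0, 1.0 + params.trial_jitter_sd * task_rng.standard_normal())
        d = params.depth * jitter
        if code != TARGET:
            d *= params.standard_depth_fraction
        trial_depths.append(d)
        stop = min(onset + w_len, n_task)
        modulation[onset:stop] += d * base_window[: stop - onset]
    modulation = np.clip(modulation, 0.0, None)
    task_data, task_truth = _render_sources(params, montage, n_task, fs,
                                            task_rng, modulation=modulation,
                                            return_truth=True)
    ev_samples = [(int(round((lead_in + o) * fs)), c) for o, c in events]
    task = Recording(task_data, fs, list(montage.labels), ev_samples,
                     "common_average")

    truth = {
        "params": params,
        "rest_sources": rest_truth,
        "task_sources": task_truth,
        "modulation": modulation,
        "trial_depths": np.asarray(trial_depths),
        "events": events,
    }
    return rest, task, truth


def _draw_subject_params(spec: CohortSpec, rng) -> SubjectParams:
    def draw(ms):
        return float(rng.normal(ms[0], ms[1]))
    return SubjectParams(
        mean_offset=np.clip(draw(spec.mean_offset), -0.95, 0.95),
        depth=np.clip(draw(spec.depth), -1.0, 0.5),
        peak_latency_s=np.clip(draw(spec.peak_latency_s), 0.3, 0.9),
        alpha_freq_hz=np.clip(draw(spec.alpha_freq_hz), 8.0, 12.0),
        noise_exponent=max(0.2, draw(spec.noise_exponent)),
        noise_level_uv=max(0.1, draw(spec.noise_level_uv)),
        standard_depth_fraction=spec.standard_depth_fraction,
        include_nuisance=spec.include_nuisance,
        fs=spec.fs,
        rest_duration_s=spec.rest_duration_s,
        n_stimuli=spec.n_stimuli,
        isi_s=spec.isi_s,
    )


@dataclass
class Cohort:
    """A simulated cohort: parameter draws, cognitive scores, lazy recordings.

    Recordings are large, so subjects are rendered on demand from
    deterministic per-subject seed substreams; calling :meth:`subject`
    twice with the same index returns bit-identical data.
    """

    spec: CohortSpec
    montage: Montage
    subject_params: list
    subject_seeds: list
    cognition: pd.DataFrame
    truth: pd.DataFrame

    def __len__(self) -> int:
        return self.spec.n_subjects

    def subject(self, i: int):
        """Render subject ``i``: ``(rest, task, truth)``."""
        p = replace(self.subject_params[i], subject_id=i)
        return simulate_subject(p, self.montage, seed=self.subject_seeds[i])


def simulate_cohort(spec: CohortSpec, montage: Montage | None = None) -> Cohort:
    """Draw a cohort of subjects and their cognitive test results.

    Cognitive raw scores are generated from latent traits that are linear in
    the standardised true response latency and amplitude plus an age effect
    and Gaussian noise:

    * attention and executive function load negatively on the latency of
      the alpha attenuation trough (times-to-complete grow with latency);
    * memory loads positively on the latent evoked-response amplitude
      ``|r * depth| * base_amplitude``.

    Times-to-complete (TMT-A/B, Stroop neutral/incongruent) are log-normal
    around canonical elderly means; recall scores are clipped fractions.
    About 1% of raw test entries are dropped to NaN to exercise imputation.
    """
    montage = montage or default_montage()
    root = np.random.SeedSequence(spec.master_seed)
    subj_ss, cog_ss = root.spawn(2)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                     subj_ss.spawn(spec.n_subjects)]
    prng = np.random.default_rng(subj_ss)
    params = [_draw_subject_params(spec, prng) for _ in range(spec.n_subjects)]

    rng = np.random.default_rng(cog_ss)
    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, size=n)
    lat = np.array([p.peak_latency_s for p in params])
    amp = np.array([abs(p.mean_offset * p.depth) * p.base_amplitude_uv
                    for p in params])
    z = lambda v: (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)
    lat_z, amp_z = z(lat), z(amp)
    att = (-spec.coupling_latency_attention * lat_z
           - 0.03 * (age - 70.0) + rng.standard_normal(n))
    mem = (spec.coupling_amplitude_memory * amp_z
           - 0.025 * (age - 70.0) + rng.standard_normal(n))
    exe = (-spec.coupling_latency_attention * lat_z
           - 0.03 * (age - 70.0) + rng.standard_normal(n))

    def time_to_complete(base, latent):
        return base * np.exp(-0.2 * latent + 0.1 * rng.standard_normal(n))

    def recall(latent):
        return np.clip(0.6 + 0.12 * latent + 0.05 * rng.standard_normal(n), 0.0, 1.0)

    cognition = pd.DataFrame({
        "subject": np.arange(n),
        "age": age,
        "tmt_a_s": time_to_complete(45.0, att),
        "stroop_neutral_s": time_to_complete(30.0, att),
        "tmt_b_s": time_to_complete(95.0, exe),
        "stroop_incongruent_s": time_to_complete(45.0, exe),
        "word_recall": recall(mem),
        "word_recognition": recall(mem),
        "figure_recall": recall(mem),
    })
    # sprinkle missing entries so downstream imputation is exercised
    raw_cols = cognition.columns[2:]
    miss = rng.random((n, len(raw_cols))) < 0.01
    for j, col in enumerate(raw_cols):
        cognition.loc[miss[:, j], col] = np.nan

    truth = pd.DataFrame({
        "subject": np.arange(n),
        "mean_offset": [p.mean_offset for p in params],
        "depth": [p.depth for p in params],
        "peak_latency_s": lat,
        "alpha_freq_hz": [p.alpha_freq_hz for p in params],
        "noise_level_uv": [p.noise_level_uv for p in params],
        "er_amplitude_truth": amp,
        "age": age,
        "attention_latent": att,
        "memory_latent": mem,
        "executive_latent": exe,
    })
    return Cohort(spec, montage, params, subject_seeds, cognition, truth)
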