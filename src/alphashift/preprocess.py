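"""Per-subject preprocessing: epoching, evoked responses, alpha envelopes.

Implements the standard single-subject stage of the analysis: cut the
continuous recording into stimulus-locked trials with baseline correction,
average trials into a (low-passed) evoked response, and extract the
alpha-band amplitude envelope per trial after removing the broadband evoked
component, so that the envelope reflects genuine oscillatory amplitude and
not the evoked deflection leaking into the alpha band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .filters import envelope as hilbert_envelope
from .filters import zero_phase_butterworth
from .simulate import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "Epochs", "ERTimecourse", "EnvelopeEpochs", "PeakEstimate", "AlphaPeaks",
    "broadband_filter", "epoch_and_baseline", "compute_er", "compute_envelope",
    "average_envelope", "detect_alpha_peak", "find_peak",
]


def broadband_filter(recording: Recording, band=(0.1, 45.0),
                     order: int = 4) -> Recording:
    """Wide band-pass of a continuous recording (default 0.1-45 Hz).

    The standard first preprocessing step: the 0.1 Hz edge removes drifts
    and the diverging ultra-slow tail of the 1/f background — which would
    otherwise swamp the 0-3 Hz band that carries the baseline shifts —
    while 45 Hz bounds the analysis spectrum.
    """
    data = zero_phase_butterworth(recording.data, recording.fs, "bandpass",
                                  band, order=order, axis=-1,
                                  pad_mode="reflect")
    return Recording(data, recording.fs, list(recording.sensor_labels),
                     list(recording.events), recording.reference_tag)


@dataclass
class Epochs:
    """Trial-segmented data, baseline-corrected per trial and sensor.

    ``data`` is (n_trials, n_sensors, n_samples) in microvolts; the default
    epoch spans -0.4 to 1.3 s around stimulus onset (1.7 s) with the
    baseline taken over (-0.2, -0.05) s.
    """

    data: np.ndarray
    fs: float
    t_start_s: float
    labels: list[str]                      # condition code per trial
    sensor_labels: list[str]
    baseline_window_s: tuple = (-0.2, -0.05)
    n_dropped: int = 0

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.data.shape[2]) / self.fs

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.asarray([lab == condition for lab in self.labels])


@dataclass
class ERTimecourse:
    """Trial-averaged evoked response, optionally low-passed."""

    data: np.ndarray                       # (n_sensors, n_samples)
    fs: float
    t_start_s: float
    condition: str
    lowpass_hz: float | None
    sensor_labels: list[str]

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.data.shape[1]) / self.fs


@dataclass
class EnvelopeEpochs:
    """Per-trial alpha amplitude envelopes (non-negative, microvolts).

    ``edge_mask`` flags the first and last 200 ms of each epoch where the
    band-pass/Hilbert chain is unreliable; the samples are kept, not
    trimmed, because post-stimulus statistics windows avoid them anyway.
    """

    data: np.ndarray                       # (n_trials, n_sensors, n_samples)
    fs: float
    t_start_s: float
    labels: list[str]
    sensor_labels: list[str]
    band_centers_hz: np.ndarray            # per sensor
    band_halfwidth_hz: float
    edge_mask: np.ndarray = field(default=None)

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.data.shape[2]) / self.fs


@dataclass
class PeakEstimate:
    latency_s: float
    amplitude_uv: float
    found: bool


@dataclass
class AlphaPeaks:
    """Per-sensor individual alpha peak frequencies from resting spectra."""

    freqs_hz: np.ndarray
    fallback: np.ndarray                   # True where no peak rose above 1/f


def epoch_and_baseline(recording: Recording, events=None,
                       window=(-0.4, 1.3), baseline=(-0.2, -0.05)) -> Epochs:
    """Cut a recording into baseline-corrected stimulus-locked trials.

    Trials whose window would exceed the recording bounds are dropped and
    counted in ``Epochs.n_dropped`` (and logged).  Raises if no trial fits.
    """
    events = recording.events if events is None else events
    fs = recording.fs
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    n_samp = i1 - i0
    b0 = int(round((baseline[0] - window[0]) * fs))
    b1 = int(round((baseline[1] - window[0]) * fs))
    trials, labels, dropped = [], [], 0
    for onset, code in events:
        lo, hi = onset + i0, onset + i0 + n_samp
        if lo < 0 or hi > recording.n_samples:
            dropped += 1
            continue
        seg = recording.data[:, lo:hi].copy()
        seg -= seg[:, b0:b1].mean(axis=1, keepdims=True)
        trials.append(seg)
        labels.append(code)
    if dropped:
        logger.info("epoching dropped %d/%d trials outside data bounds",
                    dropped, len(events))
    if not trials:
        raise ValueError("no usable trials: all events fall outside the data")
    return Epochs(np.stack(trials), fs, window[0], labels,
                  list(recording.sensor_labels), tuple(baseline), dropped)


def compute_er(epochs: Epochs, condition: str,
               lowpass_hz: float | None = 3.0) -> ERTimecourse:
    """Average trials of one condition and low-pass the result.

    The low-pass is an order-8 zero-phase Butterworth at ``lowpass_hz``
    (pass ``None`` for the broadband evoked response).  Requires at least
    two trials of the condition.
    """
    mask = epochs.condition_mask(condition)
    if mask.sum() == 0:
        raise ValueError(f"no trials with condition {condition!r}")
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 trials of {condition!r}, got {mask.sum()}")
    er = epochs.data[mask].mean(axis=0)
    if lowpass_hz is not None:
        # reflection padding keeps the operation exactly linear in the data
        er = zero_phase_butterworth(er, epochs.fs, "lowpass", lowpass_hz,
                                    order=8, axis=-1, pad_mode="reflect")
    return ERTimecourse(er, epochs.fs, epochs.t_start_s, condition,
                        lowpass_hz, list(epochs.sensor_labels))


def compute_envelope(epochs: Epochs, alpha_peaks,
                     band_halfwidth_hz: float = 2.0,
                     edge_s: float = 0.2) -> EnvelopeEpochs:
    """Alpha amplitude envelope per trial after evoked-response subtraction.

    For every trial: subtract the broadband average evoked response of the
    trial's own condition, band-pass +-``band_halfwidth_hz`` around the
    sensor's individual alpha peak (order-4 zero-phase Butterworth), and
    take the magnitude of the analytic signal.
    """
    freqs = np.asarray(alpha_peaks.freqs_hz if isinstance(alpha_peaks, AlphaPeaks)
                       else alpha_peaks, dtype=float)
    n_trials, n_sensors, n_samples = epochs.data.shape
    if freqs.shape != (n_sensors,):
        raise ValueError("need one alpha peak frequency per sensor")
    if np.any(freqs + band_halfwidth_hz >= epochs.fs / 2.0):
        raise ValueError("alpha band exceeds the Nyquist frequency")

    residual = epochs.data.copy()
    for condition in sorted(set(epochs.labels)):
        mask = epochs.condition_mask(condition)
        if mask.sum() >= 2:
            residual[mask] -= epochs.data[mask].mean(axis=0)[np.newaxis]

    env = np.empty_like(residual)
    for s in range(n_sensors):
        band = (freqs[s] - band_halfwidth_hz, freqs[s] + band_halfwidth_hz)
        filt = zero_phase_butterworth(residual[:, s, :], epochs.fs,
                                      "bandpass", band, order=4, axis=-1)
        env[:, s, :] = hilbert_envelope(filt, axis=-1)

    n_edge = int(round(edge_s * epochs.fs))
    edge = np.zeros(n_samples, dtype=bool)
    edge[:n_edge] = True
    if n_edge:
        edge[-n_edge:] = True
    return EnvelopeEpochs(env, epochs.fs, epochs.t_start_s,
                          list(epochs.labels), list(epochs.sensor_labels),
                          freqs, band_halfwidth_hz, edge)


def average_envelope(env_epochs: EnvelopeEpochs, condition: str):
    """Trial-mean envelope of one condition, with its standard error.

    Returns ``(mean, sem)``, both (n_sensors, n_samples).
    """
    mask = np.asarray([lab == condition for lab in env_epochs.labels])
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 trials of {condition!r}")
    x = env_epochs.data[mask]
    return x.mean(axis=0), x.std(axis=0, ddof=1) / np.sqrt(mask.sum())


def detect_alpha_peak(rest: Recording, search_band=(8.0, 12.0),
                      fallback_hz: float = 10.0,
                      min_duration_s: float = 60.0,
                      min_excess: float = 0.15) -> AlphaPeaks:
    """Per-sensor individual alpha peak frequency from the resting spectrum.

    Welch spectra (2 s segments, 50% overlap) are computed per sensor; a
    straight line is fitted to the log-log spectrum over 3-30 Hz excluding
    7-13 Hz to model the 1/f background, and the peak is the largest local
    maximum of the residual inside ``search_band`` that rises at least
    ``min_excess`` decades above the trend (so that ordinary spectral
    estimation jitter on a peak-free 1/f background does not masquerade as
    an alpha peak).  Sensors without such a maximum fall back to
    ``fallback_hz`` with their flag set.
    """
    if rest.duration_s < min_duration_s:
        raise ValueError(f"resting recording shorter than {min_duration_s} s")
    if rest.fs < 2.0 * search_band[1]:
        raise ValueError("sampling rate too low for the search band")
    nperseg = int(round(2.0 * rest.fs))
    f, psd = welch(rest.data, fs=rest.fs, nperseg=nperseg,
                   noverlap=nperseg // 2, axis=-1)
    fit_mask = (f >= 3.0) & (f <= 30.0) & ~((f > 7.0) & (f < 13.0))
    band_mask = (f >= search_band[0]) & (f <= search_band[1])
    logf = np.log10(f, where=f > 0, out=np.full_like(f, -12.0))
    n_sensors = rest.data.shape[0]
    freqs = np.full(n_sensors, float(fallback_hz))
    fallback = np.ones(n_sensors, dtype=bool)
    for s in range(n_sensors):
        logp = np.log10(np.maximum(psd[s], 1e-300))
        coef = np.polyfit(logf[fit_mask], logp[fit_mask], 1)
        resid = logp - np.polyval(coef, logf)
        fb, rb = f[band_mask], resid[band_mask]
        interior = np.flatnonzero(
            (rb[1:-1] > rb[:-2]) & (rb[1:-1] >= rb[2:])
            & (rb[1:-1] > min_excess)) + 1
        if interior.size:
            best = interior[np.argmax(rb[interior])]
            freqs[s] = fb[best]
            fallback[s] = False
    if fallback.any():
        logger.info("alpha peak fallback (%.1f Hz) on %d sensor(s)",
                    fallback_hz, int(fallback.sum()))
    return AlphaPeaks(freqs, fallback)


def find_peak(er: ERTimecourse, sensor: str, window=(0.2, 1.0),
              polarity: str = "positive", fallback_s: float = 0.5) -> PeakEstimate:
    """Largest local extremum of the stated polarity in a latency window.

    When no interior extremum of the requested polarity exists,
    ``found=False`` is returned with the latency fixed at ``fallback_s``
    and the amplitude read off at that latency.
    """
    if sensor not in er.sensor_labels:
        raise KeyError(f"sensor {sensor!r} not in montage")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    x = er.data[er.sensor_labels.index(sensor)]
    t = er.times()
    sign = 1.0 if polarity == "positive" else -1.0
    y = sign * x
    in_win = (t >= window[0]) & (t <= window[1])
    idx = np.flatnonzero(in_win)
    if idx.size < 3:
        raise ValueError("peak search window too narrow for the epoch")
    interior = idx[1:-1]
    is_max = (y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1])
    cand = interior[is_max & (y[interior] > 0)]
    if cand.size == 0:
        j = int(np.argmin(np.abs(t - fallback_s)))
        return PeakEstimate(float(fallback_s), float(x[j]), False)
    best = cand[np.argmax(y[cand])]
    return PeakEstimate(float(t[best]), float(x[best]), True)
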