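"""The baseline-shift index: estimating the sign of the oscillatory mean.

An oscillation with non-zero cycle mean ``r`` leaves a "trace" proportional
to ``A(t) * r`` in the low-frequency range.  At rest, where the amplitude
``A(t)`` fluctuates spontaneously, the presence and sign of ``r`` can be
read out by correlating the alpha amplitude envelope with the low-passed
signal: moments of high alpha amplitude should coincide with a more
negative (r < 0) or more positive (r > 0) low-frequency level.

The index bins the envelope samples into equal-count amplitude bins, pairs
each bin's mean envelope with the mean of the low-passed signal over the
same samples, and reports the Pearson correlation of the bin means.  The
binning suppresses sample-level noise while preserving the monotone
envelope-to-baseline relation; equal-count bins make every bin mean equally
reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .filters import envelope as hilbert_envelope
from .filters import zero_phase_butterworth
from .preprocess import AlphaPeaks
from .simulate import Recording

__all__ = ["BSIMap", "compute_bsi", "bsi_from_signals"]


@dataclass
class BSIMap:
    """Per-sensor baseline-shift indices (Pearson r of 20 bin means)."""

    bsi: np.ndarray
    alpha_freqs_hz: np.ndarray
    n_bins: int
    duration_s: float
    sensor_labels: list[str]

    def at(self, sensor: str) -> float:
        return float(self.bsi[self.sensor_labels.index(sensor)])


def bsi_from_signals(alpha_envelope: np.ndarray, low_freq: np.ndarray,
                     n_bins: int = 20) -> float:
    """Baseline-shift index from a precomputed envelope / low-pass pair.

    Samples are sorted by envelope amplitude into ``n_bins`` equal-count
    bins (smallest to biggest amplitude); the signed low-frequency signal is
    averaged within the same bins, and the index is the Pearson correlation
    of the ``n_bins`` paired means.
    """
    alpha_envelope = np.asarray(alpha_envelope, dtype=float).ravel()
    low_freq = np.asarray(low_freq, dtype=float).ravel()
    if alpha_envelope.shape != low_freq.shape:
        raise ValueError("envelope and low-frequency signal differ in length")
    if alpha_envelope.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples")
    order = np.argsort(alpha_envelope, kind="stable")
    env_means, lf_means = [], []
    for chunk in np.array_split(order, n_bins):
        env_means.append(alpha_envelope[chunk].mean())
        lf_means.append(low_freq[chunk].mean())
    r, _ = pearsonr(env_means, lf_means)
    return float(r)


def compute_bsi(rest: Recording, alpha_peaks, n_bins: int = 20,
                max_duration_s: float = 600.0,
                band_halfwidth_hz: float = 2.0,
                lowpass_hz: float = 3.0,
                edge_exclude_s: float = 1.0) -> BSIMap:
    """Compute the baseline-shift index per sensor from resting data.

    Uses at most the first ``max_duration_s`` seconds.  Per sensor: the
    broadband signal is band-passed +-``band_halfwidth_hz`` around the
    individual alpha peak (order-4 zero-phase Butterworth) and low-passed
    at ``lowpass_hz`` (order-8 zero-phase Butterworth); the Hilbert
    envelope of the former is binned against the latter.  The first and
    last ``edge_exclude_s`` seconds are excluded from binning to avoid
    filter transients.
    """
    if rest.duration_s < 60.0:
        raise ValueError("resting recording must be at least 60 s")
    freqs = np.asarray(alpha_peaks.freqs_hz if isinstance(alpha_peaks, AlphaPeaks)
                       else alpha_peaks, dtype=float)
    n_sensors = rest.data.shape[0]
    if freqs.shape != (n_sensors,):
        raise ValueError("need one alpha peak frequency per sensor")
    n_use = min(rest.n_samples, int(round(max_duration_s * rest.fs)))
    data = rest.data[:, :n_use]
    if n_use < n_bins:
        raise ValueError("fewer samples than bins")
    edge = int(round(edge_exclude_s * rest.fs))
    sl = slice(edge, n_use - edge if edge else n_use)
    low = zero_phase_butterworth(data, rest.fs, "lowpass", lowpass_hz,
                                 order=8, axis=-1)
    bsi = np.empty(n_sensors)
    for s in range(n_sensors):
        band = (freqs[s] - band_halfwidth_hz, freqs[s] + band_halfwidth_hz)
        alpha = zero_phase_butterworth(data[s], rest.fs, "bandpass", band, order=4)
        env = hilbert_envelope(alpha)
        bsi[s] = bsi_from_signals(env[sl], low[s, sl], n_bins)
    return BSIMap(bsi, freqs, n_bins, n_use / rest.fs, list(rest.sensor_labels))
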