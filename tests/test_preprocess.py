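"""Filtering, epoching, evoked-response and envelope extraction tests."""

import numpy as np
import pytest

from alphashift.filters import FilterDesignError, envelope, zero_phase_butterworth
from alphashift.preprocess import (
    ERTimecourse,
    Epochs,
    average_envelope,
    compute_envelope,
    compute_er,
    detect_alpha_peak,
    epoch_and_baseline,
    find_peak,
)
from alphashift.simulate import ModulationProfile, Recording, evaluate_modulation, oneoverf_noise


def fft_amplitude(x, fs, freq):
    """Independent single-bin amplitude estimate via projection."""
    t = np.arange(x.size) / fs
    c = np.mean(x * np.exp(-2j * np.pi * freq * t))
    return 2 * np.abs(c)


class TestZeroPhaseButterworth:
    def test_dc_passes_lowpass_unchanged(self):
        x = np.full(2000, 5.0)
        y = zero_phase_butterworth(x, 250.0, "lowpass", 3.0, 8)
        assert np.allclose(y, 5.0, atol=1e-8)

    def test_bandpass_preserves_in_band_tone(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = zero_phase_butterworth(x, fs, "bandpass", (8.0, 12.0), 4)
        mid = slice(int(2 * fs), int(8 * fs))
        assert fft_amplitude(y[mid], fs, 10.0) == pytest.approx(
            fft_amplitude(x[mid], fs, 10.0), rel=0.01)

    def test_lowpass_rejects_out_of_band_tone(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = zero_phase_butterworth(x, fs, "lowpass", 3.0, 8)
        assert np.abs(y[int(2 * fs):int(8 * fs)]).max() < 0.01

    def test_zero_phase_time_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        fwd = zero_phase_butterworth(x, 250.0, "bandpass", (8.0, 12.0), 4)
        rev = zero_phase_butterworth(x[::-1], 250.0, "bandpass",
                                     (8.0, 12.0), 4)[::-1]
        # identical away from the narrow-band edge transients
        core = slice(1000, -1000)
        assert np.allclose(fwd[core], rev[core],
                           atol=2e-3 * np.abs(fwd).max())

    def test_no_phase_delay_on_in_band_tone(self):
        fs = 250.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = zero_phase_butterworth(x, fs, "bandpass", (8.0, 12.0), 4)
        mid = slice(int(5 * fs), int(15 * fs))
        # zero-lag correlation must dominate any +-1 sample shift
        r0 = np.dot(x[mid], y[mid])
        r_plus = np.dot(x[mid], np.roll(y, 1)[mid])
        r_minus = np.dot(x[mid], np.roll(y, -1)[mid])
        assert r0 > r_plus and r0 > r_minus

    @pytest.mark.parametrize("cutoff", [0.0, 200.0, -1.0])
    def test_invalid_cutoffs_rejected(self, cutoff):
        with pytest.raises(FilterDesignError):
            zero_phase_butterworth(np.zeros(1000), 250.0, "lowpass", cutoff, 4)


class TestAlphaPeakDetection:
    def _rest(self, freqs, fs=250.0, duration=90.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration * fs)
        t = np.arange(n) / fs
        rows = []
        for f in freqs:
            x = 2.0 * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x = x + 1.5 * oneoverf_noise(n, fs, 1.0, rng)
            rows.append(x)
        labels = [f"S{i}" for i in range(len(freqs))]
        return Recording(np.array(rows), fs, labels, [], "other")

    def test_known_peak_recovered(self):
        rest = self._rest([10.4])
        peaks = detect_alpha_peak(rest)
        assert abs(peaks.freqs_hz[0] - 10.4) <= 0.3
        assert not peaks.fallback[0]

    def test_pure_noise_falls_back_with_flag(self):
        rng = np.random.default_rng(1)
        n = int(90 * 250)
        x = oneoverf_noise(n, 250.0, 1.0, rng)
        rest = Recording(x[np.newaxis], 250.0, ["S0"], [], "other")
        peaks = detect_alpha_peak(rest)
        assert peaks.fallback[0]
        assert peaks.freqs_hz[0] == 10.0

    def test_per_sensor_peaks_recovered(self):
        rest = self._rest([9.0, 11.0])
        peaks = detect_alpha_peak(rest)
        assert abs(peaks.freqs_hz[0] - 9.0) <= 0.3
        assert abs(peaks.freqs_hz[1] - 11.0) <= 0.3

    def test_short_recording_rejected(self):
        rest = self._rest([10.0], duration=30.0)
        with pytest.raises(ValueError):
            detect_alpha_peak(rest)


class TestEpoching:
    def test_constant_channel_epochs_to_zero(self):
        fs = 250.0
        rec = Recording(np.full((1, int(20 * fs)), 5.0), fs, ["Pz"],
                        [(int(5 * fs), "standard"), (int(10 * fs), "target")],
                        "other")
        ep = epoch_and_baseline(rec)
        assert np.allclose(ep.data, 0.0)

    def test_study_epoch_geometry(self):
        # a 600-event session yields 600 trials of 1700 samples at 1000 Hz
        fs = 1000.0
        n = int(2 + 600 * 1.5 + 2) * int(fs)
        events = [(int((2 + i * 1.5) * fs), "standard") for i in range(600)]
        rec = Recording(np.zeros((1, n)), fs, ["Pz"], events, "other")
        ep = epoch_and_baseline(rec)
        assert ep.data.shape == (600, 1, 1700)
        assert ep.t_start_s == -0.4

    def test_out_of_bounds_trial_dropped_and_counted(self):
        # an event 100 samples in cannot honour a -0.4 s pre-stimulus window
        fs = 1000.0
        rec = Recording(np.zeros((1, int(10 * fs))), fs, ["Pz"],
                        [(100, "target"), (int(5 * fs), "target")], "other")
        ep = epoch_and_baseline(rec)
        assert ep.n_trials == 1
        assert ep.n_dropped == 1
        assert ep.n_trials + ep.n_dropped == 2

    def test_all_trials_out_of_bounds_raises(self):
        rec = Recording(np.zeros((1, 500)), 250.0, ["Pz"], [(5, "target")],
                        "other")
        with pytest.raises(ValueError):
            epoch_and_baseline(rec)


def _epochs_from_trials(trials, fs, labels, t_start=-0.4):
    trials = np.asarray(trials, dtype=float)
    return Epochs(trials, fs, t_start, labels,
                  [f"S{i}" for i in range(trials.shape[1])])


class TestComputeEr:
    def test_identical_trials_equal_lowpassed_single_trial(self):
        fs = 250.0
        t = -0.4 + np.arange(int(1.7 * fs)) / fs
        x = np.exp(-((t - 0.5) ** 2) / 0.02)
        trials = np.stack([x[np.newaxis]] * 4)
        ep = _epochs_from_trials(trials, fs, ["target"] * 4)
        er = compute_er(ep, "target", 3.0)
        single = zero_phase_butterworth(x, fs, "lowpass", 3.0, 8,
                                        pad_mode="reflect")
        assert np.allclose(er.data[0], single)

    def test_er_is_linear_in_the_data(self):
        fs = 250.0
        rng = np.random.default_rng(0)
        a = rng.standard_normal((6, 2, int(1.7 * fs)))
        b = rng.standard_normal((6, 2, int(1.7 * fs)))
        labels = ["target"] * 6
        er_a = compute_er(_epochs_from_trials(a, fs, labels), "target").data
        er_b = compute_er(_epochs_from_trials(b, fs, labels), "target").data
        er_ab = compute_er(_epochs_from_trials(a + b, fs, labels),
                           "target").data
        assert np.allclose(er_ab, er_a + er_b, atol=1e-10)

    def test_unknown_condition_raises(self):
        ep = _epochs_from_trials(np.zeros((3, 1, 500)), 250.0, ["target"] * 3)
        with pytest.raises(ValueError):
            compute_er(ep, "oddball")


class TestEnvelope:
    def test_analytic_signal_identity_for_pure_tone(self):
        fs = 250.0
        n = int(1.7 * fs)
        t = np.arange(n) / fs
        # evenly spaced phases: the broadband average ER cancels exactly,
        # isolating the analytic-signal identity itself
        trials = np.stack([
            np.cos(2 * np.pi * 10 * t + 2 * np.pi * k / 8)[np.newaxis]
            for k in range(8)])
        ep = _epochs_from_trials(trials, fs, ["target"] * 8)
        env = compute_envelope(ep, np.array([10.0]))
        interior = ~env.edge_mask
        assert np.allclose(env.data[:, 0, interior], 1.0, atol=0.02)

    def test_envelope_tracks_known_modulation(self):
        fs = 250.0
        n = int(1.7 * fs)
        tt = np.arange(n) / fs
        prof = ModulationProfile(1.0, -0.5, onset_s=0.6, peak_latency_s=0.9,
                                 duration_s=0.6)
        a_true = evaluate_modulation(prof, tt)
        trials = np.stack([
            (a_true * np.cos(2 * np.pi * 10 * tt
                             + 2 * np.pi * k / 8))[np.newaxis]
            for k in range(8)])
        ep = _epochs_from_trials(trials, fs, ["target"] * 8)
        env = compute_envelope(ep, np.array([10.0]))
        interior = ~env.edge_mask
        rel = np.abs(env.data[:, 0, interior] - a_true[interior]) / a_true[interior]
        assert rel.mean() < 0.05

    def test_envelope_invariant_to_sign_flip(self):
        rng = np.random.default_rng(5)
        trials = rng.standard_normal((4, 1, 500))
        ep = _epochs_from_trials(trials, 250.0, ["target"] * 4)
        ep_neg = _epochs_from_trials(-trials, 250.0, ["target"] * 4)
        e1 = compute_envelope(ep, np.array([10.0])).data
        e2 = compute_envelope(ep_neg, np.array([10.0])).data
        assert np.allclose(e1, e2, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        ep = _epochs_from_trials(np.zeros((3, 1, 500)), 25.0, ["target"] * 3)
        with pytest.raises(ValueError):
            compute_envelope(ep, np.array([11.5]))

    def test_average_envelope_basics(self):
        trials = np.abs(np.random.default_rng(6).standard_normal((5, 2, 400)))
        ep = _epochs_from_trials(trials, 250.0, ["target"] * 5)
        env = compute_envelope(ep, np.array([10.0, 10.0]))
        mean, sem = average_envelope(env, "target")
        assert mean.shape == (2, 400)
        assert np.all(mean >= 0)
        assert np.all(sem >= 0)


class TestFindPeak:
    def _er(self, x, fs=250.0):
        return ERTimecourse(np.asarray(x)[np.newaxis], fs, -0.4, "target",
                            3.0, ["Pz"])

    def test_constructed_bump_located_exactly(self):
        fs = 250.0
        t = -0.4 + np.arange(int(1.7 * fs)) / fs
        x = np.where(np.abs(t - 0.5) < 0.1,
                     2.0 * (0.5 + 0.5 * np.cos(np.pi * (t - 0.5) / 0.1)), 0.0)
        pk = find_peak(self._er(x), "Pz")
        assert pk.found
        assert pk.latency_s == pytest.approx(0.5, abs=1 / fs)
        assert pk.amplitude_uv == pytest.approx(2.0, rel=1e-6)

    def test_monotone_ramp_falls_back_to_500ms(self):
        fs = 250.0
        x = np.linspace(0, 1, int(1.7 * fs))
        pk = find_peak(self._er(x), "Pz")
        assert not pk.found
        assert pk.latency_s == 0.5

    def test_larger_of_two_bumps_wins(self):
        fs = 250.0
        t = -0.4 + np.arange(int(1.7 * fs)) / fs
        x = (1.0 * np.exp(-((t - 0.3) ** 2) / 0.002)
             + 1.5 * np.exp(-((t - 0.6) ** 2) / 0.002))
        # brute-force oracle: argmax over local maxima inside the window
        inside = (t >= 0.2) & (t <= 1.0)
        ii = np.flatnonzero(inside)[1:-1]
        local = ii[(x[ii] > x[ii - 1]) & (x[ii] >= x[ii + 1])]
        expected_t = t[local[np.argmax(x[local])]]
        pk = find_peak(self._er(x), "Pz")
        assert pk.latency_s == pytest.approx(expected_t, abs=1e-9)
        assert pk.latency_s == pytest.approx(0.6, abs=0.01)

    def test_negative_polarity_search(self):
        fs = 250.0
        t = -0.4 + np.arange(int(1.7 * fs)) / fs
        x = -1.2 * np.exp(-((t - 0.4) ** 2) / 0.002)
        pk = find_peak(self._er(x), "Pz", polarity="negative")
        assert pk.found
        assert pk.amplitude_uv == pytest.approx(-1.2, rel=1e-6)

    def test_unknown_sensor_raises(self):
        with pytest.raises(KeyError):
            find_peak(self._er(np.zeros(500)), "Cz")
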