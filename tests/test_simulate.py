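"""Generative-model tests: modulation windows, oscillator, events, subjects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphashift.filters import zero_phase_butterworth
from alphashift.simulate import (
    AliasingError,
    CohortSpec,
    ModulationProfile,
    OscillatorSpec,
    SubjectParams,
    evaluate_modulation,
    generate_oddball_events,
    simulate_cohort,
    simulate_oscillation,
    simulate_population_sync_sweep,
    simulate_subject,
)
from alphashift.simulate import InvalidProfileError


class TestModulation:
    def test_no_modulation_is_flat(self):
        t = np.linspace(0, 2, 501)
        prof = ModulationProfile(baseline_level=1.3, depth=0.0)
        assert np.allclose(evaluate_modulation(prof, t), 1.3)

    def test_full_attenuation_reaches_zero_at_trough(self):
        prof = ModulationProfile(baseline_level=1.0, depth=-1.0,
                                 onset_s=0.2, peak_latency_s=0.5,
                                 duration_s=1.0)
        a = evaluate_modulation(prof, np.array([0.0, 0.5, 2.0]))
        assert a[1] == pytest.approx(0.0, abs=1e-12)
        assert a[0] == a[2] == 1.0

    def test_raised_cosine_midpoint_matches_direct_formula(self):
        # independent closed-form evaluation of the half-cosine rise at the
        # midpoint between onset (0.2 s) and trough (0.5 s): w = 1/2, so
        # A = 1 + depth/2 = 0.75 for depth -0.5
        prof = ModulationProfile(1.0, -0.5, onset_s=0.2, peak_latency_s=0.5,
                                 duration_s=1.0)
        mid = 0.35
        w_direct = 0.5 - 0.5 * np.cos(np.pi * (mid - 0.2) / (0.5 - 0.2))
        expected = 1.0 + (-0.5) * w_direct
        assert expected == pytest.approx(0.75)
        got = evaluate_modulation(prof, np.array([0.0, mid]))[1]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_depth_below_minus_one_rejected(self):
        with pytest.raises(InvalidProfileError):
            ModulationProfile(depth=-1.2)

    @settings(derandomize=True, max_examples=40)
    @given(depth=st.floats(-1.0, 1.0), base=st.floats(0.1, 10.0))
    def test_trace_nonnegative_and_flat_outside_window(self, depth, base):
        prof = ModulationProfile(base, depth)
        t = np.linspace(-0.4, 2.0, 601)
        a = evaluate_modulation(prof, t)
        assert np.all(a >= 0)
        outside = (t < prof.onset_s) | (t > prof.onset_s + prof.duration_s)
        assert np.allclose(a[outside], base)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            evaluate_modulation(ModulationProfile(), np.array([0.0, 1.0, 0.5]))


class TestOscillator:
    def test_zero_mean_sinusoid_has_zero_time_mean(self):
        spec = OscillatorSpec(10.0, mean_offset=0.0, base_amplitude=2.0)
        y = simulate_oscillation(spec, ModulationProfile(), 2.0, 500.0, seed=0)
        assert abs(y.mean()) < 1e-6 * 2.0

    def test_offset_survives_in_time_mean(self):
        spec = OscillatorSpec(10.0, mean_offset=0.2, base_amplitude=1.0)
        y = simulate_oscillation(spec, ModulationProfile(), 2.0, 500.0, seed=0)
        assert y.mean() == pytest.approx(0.2, abs=1e-6)

    def test_lowpass_recovers_baseline_shift(self):
        # oracle: low-pass the analytic baseline shift A(t)*r with the same
        # filter and compare away from the epoch edges
        fs, dur, r = 500.0, 4.0, -0.5
        prof = ModulationProfile(1.0, -0.6, onset_s=1.5, peak_latency_s=1.9,
                                 duration_s=1.0)
        spec = OscillatorSpec(10.0, mean_offset=r, base_amplitude=1.0)
        y = simulate_oscillation(spec, prof, dur, fs, seed=1)
        t = np.arange(int(dur * fs)) / fs
        shift_true = evaluate_modulation(prof, t) * r
        lp = zero_phase_butterworth(y, fs, "lowpass", 3.0, 8)
        lp_true = zero_phase_butterworth(shift_true, fs, "lowpass", 3.0, 8)
        # a full second clears the order-8 low-pass settling transient
        interior = slice(int(1.0 * fs), int(3.0 * fs))
        err = np.max(np.abs(lp[interior] - lp_true[interior]))
        assert err < 0.05 * np.max(np.abs(shift_true))

    def test_population_resultant_matches_explicit_unit_sum(self):
        # oracle: materialise every unit's phase and average the cosines
        spec = OscillatorSpec(10.0, phase_rad=0.7, mean_offset=-0.3,
                              base_amplitude=2.0, n_units=32, sync=0.5)
        prof = ModulationProfile(1.0, -0.5)
        fs, dur = 250.0, 2.0
        y = simulate_oscillation(spec, prof, dur, fs, seed=42)
        rng = np.random.default_rng(42)
        n_sync = round(spec.sync * spec.n_units)
        phases = np.full(spec.n_units, spec.phase_rad)
        phases[n_sync:] = rng.uniform(0, 2 * np.pi, spec.n_units - n_sync)
        t = np.arange(int(dur * fs)) / fs
        a = evaluate_modulation(prof, t) * spec.base_amplitude
        units = np.cos(2 * np.pi * 10.0 * t[np.newaxis]
                       + phases[:, np.newaxis]).mean(axis=0)
        expected = a * (units + spec.mean_offset)
        assert np.allclose(y, expected, atol=1e-10)

    def test_aliasing_raises(self):
        with pytest.raises(AliasingError):
            simulate_oscillation(OscillatorSpec(10.0), ModulationProfile(),
                                 2.0, 15.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            simulate_oscillation(OscillatorSpec(10.0), ModulationProfile(),
                                 0.5, 500.0)


class TestSyncSweep:
    def test_envelope_grows_with_sync_but_shift_does_not(self):
        spec = OscillatorSpec(10.0, mean_offset=-0.5, base_amplitude=1.0,
                              n_units=500)
        prof = ModulationProfile(1.0, -0.5, onset_s=1.0, peak_latency_s=1.4,
                                 duration_s=1.0)
        table = simulate_population_sync_sweep(
            spec, prof, [0.0, 1.0], seed=7, n_trials=40, duration_s=3.0,
            fs=250.0)
        env = table.set_index("sync")["envelope_modulation"]
        shift = table.set_index("sync")["baseline_shift"]
        assert env[1.0] > env[0.0]
        assert abs(shift[0.0] - shift[1.0]) / shift[1.0] < 0.1

    def test_no_offset_no_shift(self):
        spec = OscillatorSpec(10.0, mean_offset=0.0, base_amplitude=1.0,
                              n_units=200)
        prof = ModulationProfile(1.0, -0.5, onset_s=1.0, peak_latency_s=1.4,
                                 duration_s=1.0)
        table = simulate_population_sync_sweep(spec, prof, [0.5], seed=3,
                                               n_trials=40, duration_s=3.0,
                                               fs=250.0)
        # the residual shift is pure Monte-Carlo leakage of the carrier
        assert table["baseline_shift"].iloc[0] < 0.02

    def test_single_unit_sweep_rejected(self):
        with pytest.raises(ValueError):
            simulate_population_sync_sweep(
                OscillatorSpec(10.0, n_units=1), ModulationProfile(), [0, 1])


def scan_sequence(codes, min_between=2, max_run=9):
    """Brute-force constraint check, independent of the generator."""
    run = 0
    max_run_seen = 0
    gaps_ok = True
    last_target = None
    for i, c in enumerate(codes):
        run = run + 1 if c == "standard" else 0
        max_run_seen = max(max_run_seen, run)
        if c == "target":
            if last_target is not None:
                between = codes[last_target + 1:i]
                if sum(1 for b in between if b == "standard") < min_between:
                    gaps_ok = False
            last_target = i
    return max_run_seen <= max_run and gaps_ok


class TestOddballEvents:
    def test_category_counts_match_probabilities(self):
        ev = generate_oddball_events(600, seed=0)
        codes = [c for _, c in ev]
        assert len(ev) == 600
        assert codes.count("standard") == 456
        assert codes.count("target") == 72
        assert codes.count("novelty") == 72

    def test_onsets_spaced_exactly_isi(self):
        ev = generate_oddball_events(100, isi_s=1.5, seed=2)
        onsets = np.array([o for o, _ in ev])
        assert np.allclose(np.diff(onsets), 1.5)

    @pytest.mark.parametrize("seed", range(40))
    def test_constraints_hold_by_exhaustive_scan(self, seed):
        ev = generate_oddball_events(600, seed=seed)
        assert scan_sequence([c for _, c in ev])

    def test_infeasible_counts_raise(self):
        from alphashift.simulate import SequenceConstraintError
        with pytest.raises(SequenceConstraintError):
            # 50% targets cannot keep 2 standards between targets
            generate_oddball_events(100, proportions=(0.2, 0.5, 0.3), seed=0)

    def test_same_seed_reproduces_sequence(self):
        assert (generate_oddball_events(300, seed=9)
                == generate_oddball_events(300, seed=9))


def _tiny_params(**kw):
    defaults = dict(fs=250.0, rest_duration_s=10.0, n_stimuli=80,
                    noise_level_uv=0.0, trial_jitter_sd=0.0,
                    include_nuisance=False)
    defaults.update(kw)
    return SubjectParams(**defaults)


def _er_peak_at(task, montage, sensor="Pz", window=(0.3, 0.7)):
    from alphashift.preprocess import compute_er, epoch_and_baseline
    ep = epoch_and_baseline(task)
    er = compute_er(ep, "target", 3.0)
    t = er.times()
    sel = (t >= window[0]) & (t <= window[1])
    return er.data[er.sensor_labels.index(sensor)][sel]


class TestSubjectTriad:
    """The mechanism needs both a non-zero mean and a modulation."""

    def test_negative_mean_plus_attenuation_gives_positive_er(self, montage):
        p = _tiny_params(mean_offset=-0.5, depth=-0.6)
        _, task, _ = simulate_subject(p, montage, seed=11)
        seg = _er_peak_at(task, montage)
        assert seg.max() > 0.3   # ~ |r * depth| * A = 1.5 uV at the source

    def test_zero_mean_gives_no_er(self, montage):
        p = _tiny_params(mean_offset=0.0, depth=-0.6)
        _, task, _ = simulate_subject(p, montage, seed=11)
        ref = _er_peak_at(task, montage)
        p2 = _tiny_params(mean_offset=-0.5, depth=-0.6)
        _, task2, _ = simulate_subject(p2, montage, seed=11)
        assert np.abs(ref).max() < 0.2 * _er_peak_at(task2, montage).max()

    def test_no_modulation_gives_no_er(self, montage):
        p = _tiny_params(mean_offset=-0.5, depth=0.0,
                         standard_depth_fraction=0.0)
        _, task, _ = simulate_subject(p, montage, seed=11)
        ref = _er_peak_at(task, montage)
        p2 = _tiny_params(mean_offset=-0.5, depth=-0.6)
        _, task2, _ = simulate_subject(p2, montage, seed=11)
        assert np.abs(ref).max() < 0.2 * _er_peak_at(task2, montage).max()

    def test_er_is_linear_in_mean_offset(self):
        # trial-averaged low-passed ER of a population with random per-trial
        # carrier phase: doubling r doubles the deflection, envelope unchanged
        fs, dur = 250.0, 3.0
        prof = ModulationProfile(1.0, -0.5, onset_s=1.0, peak_latency_s=1.4,
                                 duration_s=1.0)
        t = np.arange(int(dur * fs)) / fs
        interior = (t >= 0.75) & (t <= dur - 0.75)
        pre = (t < 1.0) & interior

        def er_amp(r, seed):
            rng = np.random.default_rng(seed)
            spec = OscillatorSpec(10.0, mean_offset=r, sync=0.0)
            trials = np.stack([
                simulate_oscillation(spec, prof, dur, fs,
                                     seed=rng.integers(2**31))
                for _ in range(100)])
            lp = zero_phase_butterworth(trials.mean(axis=0), fs, "lowpass",
                                        3.0, 8)
            dev = lp[interior] - lp[pre].mean()
            return dev[np.abs(dev).argmax()]

        a1, a2 = er_amp(-0.25, 0), er_amp(-0.5, 0)
        assert a2 == pytest.approx(2.0 * a1, rel=0.02)

    def test_er_floor_scales_as_inverse_sqrt_trials(self):
        # with r = 0 the residual ER is carrier leakage that averages out as
        # 1/sqrt(n_trials); check the log-log slope over a 16-fold range
        fs = 250.0
        rng = np.random.default_rng(0)
        n_samples = int(1.7 * fs)
        spec = OscillatorSpec(10.0, mean_offset=0.0, sync=0.0)
        prof = ModulationProfile(1.0, 0.0)
        long = {n: [] for n in (50, 200, 800)}
        for rep in range(20):
            trials = np.stack([
                simulate_oscillation(spec, prof, 1.7, fs,
                                     seed=rng.integers(2**31))
                for _ in range(800)])
            for n in long:
                er = trials[:n].mean(axis=0)
                long[n].append(np.abs(er).max())
        # RMS across repetitions: E[max^2] ~ E|resultant|^2 = 1/n exactly
        floors = np.array([np.sqrt(np.mean(np.square(long[n])))
                           for n in (50, 200, 800)])
        slope = np.polyfit(np.log([50, 200, 800]), np.log(floors), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestCohort:
    def test_same_master_seed_is_bit_identical(self, montage):
        spec = CohortSpec(n_subjects=2, master_seed=5, fs=250.0,
                          rest_duration_s=10.0, n_stimuli=20)
        c1 = simulate_cohort(spec, montage)
        c2 = simulate_cohort(spec, montage)
        r1, t1, _ = c1.subject(1)
        r2, t2, _ = c2.subject(1)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(t1.data, t2.data)
        assert c1.cognition.equals(c2.cognition)

    def test_null_coupling_decorrelates_scores_from_latency(self, montage):
        spec = CohortSpec(n_subjects=400, master_seed=2,
                          coupling_latency_attention=0.0,
                          coupling_amplitude_memory=0.0)
        c = simulate_cohort(spec, montage)
        lat = c.truth["peak_latency_s"]
        att = c.truth["attention_latent"] + 0.03 * (c.truth["age"] - 70)
        r = np.corrcoef(lat, att)[0, 1]
        assert abs(r) < 0.12

    def test_positive_coupling_recovered_by_regression(self, montage):
        spec = CohortSpec(n_subjects=500, master_seed=3,
                          coupling_latency_attention=0.8)
        c = simulate_cohort(spec, montage)
        lat = c.truth["peak_latency_s"].to_numpy()
        att = c.truth["attention_latent"].to_numpy()
        age = c.truth["age"].to_numpy()
        beta = np.linalg.lstsq(
            np.column_stack([np.ones_like(lat), lat, age]), att, rcond=None)[0][1]
        assert beta < 0  # longer latency -> worse attention
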