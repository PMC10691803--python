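"""End-to-end orchestration: simulate, preprocess, test the four predictions.

The prediction suite ties the stages together the way the underlying study
design does:

1. *Temporal similarity* — grand-average evoked response (ER) and alpha
   envelope time courses are correlated per sensor; under the
   baseline-shift mechanism the correlation is negative over parietal
   sensors.
2. *Spatial similarity* — target-vs-standard contrast topographies of ER
   amplitude and alpha envelope ratio, compared by Spearman rank
   correlation at the ER peak.
3. *Non-zero mean* — resting-state baseline-shift indices (BSI); subjects
   binned by BSI at the peak sensor, ER of extreme bins contrasted with
   the spatio-temporal cluster permutation test.  A parallel binning by
   envelope modulation depth checks that deeper alpha attenuation goes
   with larger ER.
4. *Cognition* — spatially filtered (LDA / CSP) P300 and alpha envelope
   parameters are associated with composite cognitive scores (age
   adjusted), and the P300-cognition link is tested for mediation through
   the alpha parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, bsi as bsi_mod, preprocess as pp, spatial, stats
from .config import PipelineConfig, save_config
from .filters import envelope as hilbert_envelope
from .filters import zero_phase_butterworth
from .montage import Montage, default_montage, sensor_adjacency
from .simulate import Cohort, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["SubjectDerived", "preprocess_subject", "preprocess_cohort",
           "run_prediction_suite", "save_derived", "load_derived"]


@dataclass
class SubjectDerived:
    """Compact per-subject derived quantities kept in memory for the cohort."""

    er_target: np.ndarray        # (n_sensors, n_samples) low-passed
    er_standard: np.ndarray
    env_target: np.ndarray       # trial-mean envelope per condition
    env_standard: np.ndarray
    bsi: np.ndarray              # per sensor
    alpha_freqs: np.ndarray
    peak_latency_s: float
    peak_amplitude_uv: float
    peak_found: bool
    env_change_pct: float
    env_trough_s: float
    lda_target: np.ndarray       # train-window ER amplitude per sensor
    lda_standard: np.ndarray
    cov_target: np.ndarray       # alpha-band trial covariance (train window)
    cov_standard: np.ndarray
    fs: float
    t_start_s: float


def _train_window_cov(epochs, freqs, config, condition):
    """Trial-averaged covariance of alpha-filtered data in the train window."""
    f0 = float(np.median(freqs))
    band = (f0 - config.alpha_band_halfwidth_hz,
            f0 + config.alpha_band_halfwidth_hz)
    filt = zero_phase_butterworth(epochs.data, epochs.fs, "bandpass", band,
                                  order=config.alpha_filter_order, axis=-1)
    t = epochs.times()
    sel = (t >= config.train_window_s[0]) & (t <= config.train_window_s[1])
    mask = epochs.condition_mask(condition)
    covs = [np.cov(trial[:, sel]) for trial in filt[mask]]
    return np.mean(covs, axis=0)


def preprocess_subject(rest, task, config: PipelineConfig,
                       compute_rest_bsi: bool = True) -> SubjectDerived:
    """Run the full single-subject stage and keep only compact summaries."""
    rest = pp.broadband_filter(rest)
    peaks = pp.detect_alpha_peak(rest, min_duration_s=min(60.0, rest.duration_s))
    epochs = pp.epoch_and_baseline(task, window=config.epoch_window_s,
                                   baseline=config.baseline_window_s)
    er_t = pp.compute_er(epochs, "target", config.lowpass_hz)
    er_s = pp.compute_er(epochs, "standard", config.lowpass_hz)
    env = pp.compute_envelope(epochs, peaks,
                              band_halfwidth_hz=config.alpha_band_halfwidth_hz)
    env_t, _ = pp.average_envelope(env, "target")
    env_s, _ = pp.average_envelope(env, "standard")
    peak = pp.find_peak(er_t, config.peak_sensor, window=config.peak_window_s)
    pz = er_t.sensor_labels.index(config.peak_sensor)
    summ = stats.summarize_envelope(env_t[pz], epochs.fs, epochs.t_start_s,
                                    baseline=config.baseline_window_s,
                                    post_window=config.post_window_s)
    t = er_t.times()
    train = (t >= config.train_window_s[0]) & (t <= config.train_window_s[1])
    bsi_map = (bsi_mod.compute_bsi(rest, peaks, n_bins=config.n_bsi_bins)
               if compute_rest_bsi
               else None)
    return SubjectDerived(
        er_target=er_t.data.astype(np.float32),
        er_standard=er_s.data.astype(np.float32),
        env_target=env_t.astype(np.float32),
        env_standard=env_s.astype(np.float32),
        bsi=(bsi_map.bsi if bsi_map is not None
             else np.full(len(task.sensor_labels), np.nan)),
        alpha_freqs=peaks.freqs_hz,
        peak_latency_s=peak.latency_s,
        peak_amplitude_uv=peak.amplitude_uv,
        peak_found=peak.found,
        env_change_pct=summ.normalized_change_pct,
        env_trough_s=summ.trough_latency_s,
        lda_target=er_t.data[:, train].mean(axis=1),
        lda_standard=er_s.data[:, train].mean(axis=1),
        cov_target=_train_window_cov(epochs, peaks.freqs_hz, config, "target"),
        cov_standard=_train_window_cov(epochs, peaks.freqs_hz, config, "standard"),
        fs=epochs.fs,
        t_start_s=epochs.t_start_s,
    )


_SCALAR_FIELDS = ("peak_latency_s", "peak_amplitude_uv", "peak_found",
                  "env_change_pct", "env_trough_s", "fs", "t_start_s")


def save_derived(derived: SubjectDerived, path) -> None:
    """Cache one subject's derived quantities as a compressed npz."""
    arrays = {f.name: getattr(derived, f.name)
              for f in dataclasses.fields(SubjectDerived)}
    np.savez_compressed(path, **arrays)


def load_derived(path) -> SubjectDerived:
    with np.load(path) as z:
        kwargs = {}
        for f in dataclasses.fields(SubjectDerived):
            val = z[f.name]
            if f.name in _SCALAR_FIELDS:
                val = val.item()
            kwargs[f.name] = val
    return SubjectDerived(**kwargs)


def preprocess_cohort(cohort, config: PipelineConfig,
                      cache_dir=None) -> list:
    """Preprocess every subject, optionally caching per-subject npz files."""
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    derived = []
    for i in range(len(cohort)):
        f = cache / f"subject_{i:04d}.npz" if cache is not None else None
        if f is not None and f.exists():
            derived.append(load_derived(f))
            continue
        rest, task, _ = cohort.subject(i)
        d = preprocess_subject(rest, task, config)
        if f is not None:
            save_derived(d, f)
        derived.append(d)
        logger.info("preprocessed subject %d/%d", i + 1, len(cohort))
    return derived


def _csp_envelope_summary(task, filt, freqs, config):
    """Virtual-channel alpha envelope summary for one subject."""
    epochs = pp.epoch_and_baseline(task, window=config.epoch_window_s,
                                   baseline=config.baseline_window_s)
    f0 = float(np.median(freqs))
    band = (f0 - config.alpha_band_halfwidth_hz,
            f0 + config.alpha_band_halfwidth_hz)
    virt = spatial.apply_filter(filt, epochs.data)          # (trials, samples)
    virt = zero_phase_butterworth(virt, epochs.fs, "bandpass", band,
                                  order=config.alpha_filter_order, axis=-1)
    env = hilbert_envelope(virt, axis=-1)
    mask = epochs.condition_mask("target")
    mean_env = env[mask].mean(axis=0)
    return stats.summarize_envelope(mean_env, epochs.fs, epochs.t_start_s,
                                    baseline=config.baseline_window_s,
                                    post_window=config.post_window_s)


def run_prediction_suite(config: PipelineConfig, out_dir=None,
                         montage: Montage | None = None,
                         cohort: Cohort | None = None) -> dict:
    """Simulate (or accept) a cohort and evaluate the four predictions.

    Returns a report dictionary with the headline numbers of every
    prediction; when ``out_dir`` is given, tables (TSV), figures (PNG), the
    resolved configuration and a plain-text report are written there.
    """
    montage = montage or default_montage()
    if cohort is None:
        cohort = simulate_cohort(config.cohort, montage)
    n = len(cohort)
    derived = preprocess_cohort(cohort, config)

    fs = derived[0].fs
    t0 = derived[0].t_start_s
    labels = list(montage.labels)
    pz = labels.index(config.peak_sensor)
    er_t_all = np.stack([d.er_target for d in derived])      # (n, S, T)
    er_s_all = np.stack([d.er_standard for d in derived])
    env_t_all = np.stack([d.env_target for d in derived])
    env_s_all = np.stack([d.env_standard for d in derived])
    report: dict = {"n_subjects": n, "seed": config.seed}

    # -- prediction 1: temporal similarity ---------------------------------
    ga_er = er_t_all.mean(axis=0)
    ga_env = env_t_all.mean(axis=0)
    r, p, mask = stats.timecourse_correlation(
        ga_er, ga_env, fs, t0, window=(0.0, config.post_window_s[1]),
        p_base=config.bonferroni_base_p)
    report["timecourse_correlation_pz"] = float(r[pz])
    report["timecourse_significant_sensors"] = int(mask.sum())

    # -- prediction 2: spatial similarity -----------------------------------
    grand_peak = pp.find_peak(
        pp.ERTimecourse(ga_er, fs, t0, "target", config.lowpass_hz, labels),
        config.peak_sensor, window=config.peak_window_s)
    er_diff, alpha_ratio = stats.contrast_topographies(
        ga_er, er_s_all.mean(axis=0), ga_env, env_s_all.mean(axis=0),
        grand_peak, fs, t0)
    rho = stats.spearman_topography_similarity(er_diff, alpha_ratio)
    report["grand_peak_latency_s"] = grand_peak.latency_s
    report["topography_spearman_rho"] = rho

    # -- prediction 3: BSI and binning ---------------------------------------
    adjacency = sensor_adjacency(montage)
    bsi_pz = np.array([d.bsi[pz] for d in derived])
    report["bsi_pz_mean"] = float(np.nanmean(bsi_pz))
    changes = np.array([d.env_change_pct for d in derived])
    report["env_change_pct_mean"] = float(changes.mean())
    rng = np.random.default_rng(config.seed)
    cluster_out = {}
    for key, crit in (("depth", changes), ("bsi", bsi_pz)):
        if np.isnan(crit).any() or n < config.n_subject_bins * 2:
            cluster_out[key] = None
            continue
        bins = stats.quantile_bin(crit, config.n_subject_bins)
        ga_bins = [er_t_all[bins == b, pz].mean() for b in
                   range(1, config.n_subject_bins + 1)]
        res = stats.cluster_permutation_test(
            er_t_all[bins == 1], er_t_all[bins == config.n_subject_bins],
            adjacency, n_perm=config.n_permutations,
            p_thresh=config.cluster_p_threshold,
            seed=int(rng.integers(2**31)))
        cluster_out[key] = (bins, ga_bins, res)
        best_p = min((c.p_value for c in res.clusters), default=1.0)
        report[f"{key}_bin_cluster_p"] = float(best_p)
        report[f"{key}_bin_n_clusters"] = len(res.clusters)
    if cluster_out["depth"] is not None:
        bins, _, _ = cluster_out["depth"]
        t = t0 + np.arange(er_t_all.shape[2]) / fs
        train = (t >= config.train_window_s[0]) & (t <= config.train_window_s[1])
        amp_by_bin = [float(er_t_all[bins == b][:, pz, :][:, train].mean())
                      for b in range(1, config.n_subject_bins + 1)]
        report["p300_amplitude_by_depth_bin"] = amp_by_bin

    # -- prediction 4: spatial filtering, cognition, mediation ---------------
    lda = spatial.fit_lda_filter(
        np.stack([d.lda_target for d in derived]),
        np.stack([d.lda_standard for d in derived]),
        window_s=config.train_window_s)
    csp_filters = spatial.fit_csp(
        np.mean([d.cov_target for d in derived], axis=0),
        np.mean([d.cov_standard for d in derived], axis=0),
        window_s=config.train_window_s)
    csp = spatial.select_csp_component(csp_filters, er_diff)
    report["csp_eigenvalue"] = csp.eigenvalue

    p300_amp = np.empty(n)
    p300_lat = np.empty(n)
    for i, d in enumerate(derived):
        virt = spatial.apply_filter(lda, d.er_target.astype(float))
        er_virt = pp.ERTimecourse(virt[np.newaxis, :], fs, t0, "target",
                                  config.lowpass_hz, ["virtual"])
        pk = pp.find_peak(er_virt, "virtual", window=config.peak_window_s)
        p300_amp[i], p300_lat[i] = pk.amplitude_uv, pk.latency_s
    alpha_change = np.empty(n)
    alpha_lat = np.empty(n)
    for i in range(n):
        _, task, _ = cohort.subject(i)
        summ = _csp_envelope_summary(task, csp, derived[i].alpha_freqs, config)
        alpha_change[i] = summ.normalized_change_pct
        alpha_lat[i] = summ.trough_latency_s

    cog = cohort.cognition
    composites = {
        "attention": behavior.composite_score(
            cog[["tmt_a_s", "stroop_neutral_s"]].to_numpy(), [True, True]),
        "memory": behavior.composite_score(
            cog[["word_recall", "word_recognition", "figure_recall"]].to_numpy(),
            [False, False, False]),
        "executive": behavior.composite_score(
            cog[["tmt_b_s", "stroop_incongruent_s"]].to_numpy(), [True, True]),
    }
    markers = {"p300_amplitude": p300_amp, "p300_latency": p300_lat,
               "alpha_change": alpha_change, "alpha_latency": alpha_lat}
    age = cog["age"].to_numpy()
    assoc_rows = []
    for score_name, score in composites.items():
        for marker_name, marker in markers.items():
            res = behavior.regress_with_age(score, marker, age)
            assoc_rows.append((score_name, marker_name, res.beta, res.se,
                               res.p_value))
    associations = pd.DataFrame(
        assoc_rows, columns=["score", "marker", "beta", "se", "p"])
    med = behavior.mediate(p300_lat, alpha_lat, composites["attention"],
                           covariate=age, n_boot=config.n_boot,
                           seed=int(rng.integers(2**31)))
    report["mediation_prop_attention"] = med.prop_mediated
    med_exec = behavior.mediate(p300_lat, alpha_lat, composites["executive"],
                                covariate=age, n_boot=config.n_boot,
                                seed=int(rng.integers(2**31)))
    report["mediation_prop_executive"] = med_exec.prop_mediated

    if out_dir is not None:
        _write_artifacts(Path(out_dir), config, montage, report, r, p, mask,
                         er_diff, alpha_ratio, bsi_pz, changes, associations,
                         med, med_exec, ga_er, ga_env, fs, t0, pz)
    return report


def _write_artifacts(out, config, montage, report, r, p, mask, er_diff,
                     alpha_ratio, bsi_pz, changes, associations, med,
                     med_exec, ga_er, ga_env, fs, t0, pz):
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    pd.DataFrame({"sensor": montage.labels, "r": r, "p": p,
                  "significant": mask}).to_csv(
        out / "timecourse_correlation.tsv", sep="\t", index=False)
    pd.DataFrame({"sensor": montage.labels, "er_diff_uv": er_diff,
                  "alpha_ratio": alpha_ratio}).to_csv(
        out / "contrast_topographies.tsv", sep="\t", index=False)
    pd.DataFrame({"subject": np.arange(len(bsi_pz)), "bsi_pz": bsi_pz,
                  "env_change_pct": changes}).to_csv(
        out / "subject_markers.tsv", sep="\t", index=False)
    associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    med_rows = [("attention", dataclasses.asdict(med)),
                ("executive", dataclasses.asdict(med_exec))]
    with open(out / "mediation.json", "w") as fh:
        json.dump({k: v for k, v in med_rows}, fh, indent=1, default=str)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    lines = [f"{k}: {v}" for k, v in report.items()]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    _figures(out, ga_er, ga_env, fs, t0, pz, montage, er_diff, alpha_ratio,
             bsi_pz)


def _figures(out, ga_er, ga_env, fs, t0, pz, montage, er_diff, alpha_ratio,
             bsi_pz):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = t0 + np.arange(ga_er.shape[1]) / fs
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    axes[0].plot(t, ga_er[pz])
    axes[0].set(title="Grand-average ER (target)", xlabel="time (s)",
                ylabel="amplitude (uV)")
    axes[1].plot(t, ga_env[pz])
    axes[1].set(title="Alpha envelope (target)", xlabel="time (s)",
                ylabel="envelope (uV)")
    fig.tight_layout()
    fig.savefig(out / "timecourses.png", dpi=120)
    plt.close(fig)

    xy = montage.projected_2d()
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, values, title in ((axes[0], er_diff, "ER target-standard (uV)"),
                              (axes[1], alpha_ratio, "alpha ratio")):
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, cmap="RdBu_r", s=120)
        ax.set_title(title)
        ax.set_aspect("equal")
        fig.colorbar(sc, ax=ax)
    fig.tight_layout()
    fig.savefig(out / "topographies.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(bsi_pz[~np.isnan(bsi_pz)], bins=20)
    ax.set(title="BSI at peak sensor", xlabel="BSI", ylabel="subjects")
    fig.tight_layout()
    fig.savefig(out / "bsi_histogram.png", dpi=120)
    plt.close(fig)
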