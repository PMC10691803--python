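"""Cohort-level statistics for evoked responses and amplitude envelopes.

Covers the group stage of the analysis: the normalised envelope change used
to quantify modulation depth, equal-count quantile binning of subjects, the
spatio-temporal cluster-based permutation test (mass statistic, unpaired
label permutations, family-wise control via the max-cluster null),
time-course correlations with Bonferroni masking, and target-vs-standard
contrast topographies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr, rankdata
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "EnvelopeSummary", "Cluster", "ClusterResult",
    "normalized_change", "summarize_envelope", "quantile_bin",
    "cluster_permutation_test", "cluster_signflip_test",
    "timecourse_correlation", "contrast_topographies",
    "spearman_topography_similarity",
]


@dataclass
class EnvelopeSummary:
    """Pre/post-stimulus summary of a mean envelope trace.

    ``normalized_change_pct = (a_post - a_pre) / a_pre * 100``: -100%
    is the deepest possible modulation, 0% no change, positive values an
    amplitude increase.
    """

    a_pre: float
    a_post: float
    normalized_change_pct: float
    trough_latency_s: float


@dataclass
class Cluster:
    points: np.ndarray          # (k, 2) array of (sensor, sample) indices
    mass: float                 # sum of t-values over members
    p_value: float


@dataclass
class ClusterResult:
    t_map: np.ndarray           # (n_sensors, n_samples)
    clusters: list
    n_permutations: int
    threshold: float
    p_threshold: float

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_value <= alpha]


def normalized_change(a_pre: float, a_post: float) -> float:
    """Signed percent change of the envelope, ``(post - pre) / pre * 100``."""
    if a_pre <= 0:
        raise ValueError("a_pre must be positive")
    return (a_post - a_pre) / a_pre * 100.0


def summarize_envelope(trace, fs: float, t_start_s: float,
                       baseline=(-0.2, -0.05),
                       post_window=(0.2, 1.0)) -> EnvelopeSummary:
    """Summarise one envelope time course: baseline level, trough, change.

    ``a_pre`` is the baseline-window mean, the trough is the argmin of the
    envelope inside ``post_window`` (earliest sample on ties) and
    ``a_post`` is the envelope value at the trough.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    t = t_start_s + np.arange(trace.size) / fs
    pre = (t >= baseline[0]) & (t <= baseline[1])
    post = (t >= post_window[0]) & (t <= post_window[1])
    if not pre.any() or not post.any():
        raise ValueError("summary windows fall outside the epoch")
    a_pre = float(trace[pre].mean())
    post_idx = np.flatnonzero(post)
    j = post_idx[int(np.argmin(trace[post_idx]))]   # argmin takes the earliest tie
    a_post = float(trace[j])
    return EnvelopeSummary(a_pre, a_post, normalized_change(a_pre, a_post),
                           float(t[j]))


def quantile_bin(values, n_bins: int = 5) -> np.ndarray:
    """Equal-count bin index (1..n_bins) per subject; bin 1 = most negative.

    Counts differ by at most one when ``len(values)`` is not divisible by
    ``n_bins``.  Ties across a bin boundary are broken by stable input
    order (and logged).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if values.size < n_bins:
        raise ValueError("need at least n_bins subjects")
    order = np.argsort(values, kind="stable")
    bins = np.empty(values.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        bins[chunk] = b
    for b in range(1, n_bins):
        hi = values[bins == b].max()
        lo = values[bins == b + 1].min()
        if hi == lo:
            logger.info("tied values across bin boundary %d/%d resolved by "
                        "input order", b, b + 1)
    return bins


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

def _t_two_sample(xa, xb):
    """Pooled-variance two-sample t over the leading (subject) axis."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _grid_adjacency(sensor_adj: sparse.spmatrix, n_samples: int) -> sparse.csr_matrix:
    """Adjacency over the flattened (sensor, sample) grid.

    Node ``s * n_samples + j`` connects to spatial neighbours at the same
    sample and to the same sensor at samples ``j +- 1``.
    """
    n_sensors = sensor_adj.shape[0]
    eye_t = sparse.identity(n_samples, dtype=bool, format="csr")
    spatial = sparse.kron(sensor_adj.astype(bool), eye_t, format="csr")
    temporal_1d = sparse.diags([np.ones(n_samples - 1)] * 2, [-1, 1],
                               dtype=bool, format="csr")
    temporal = sparse.kron(sparse.identity(n_sensors, dtype=bool),
                           temporal_1d, format="csr")
    return (spatial + temporal).tocsr()


def _clusters_from_mask(mask_flat, t_flat, grid_adj):
    """Connected supra-threshold components and their t-mass."""
    idx = np.flatnonzero(mask_flat)
    if idx.size == 0:
        return []
    sub = grid_adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for k in range(n_comp):
        members = idx[labels == k]
        out.append((members, float(t_flat[members].sum())))
    return out


def cluster_permutation_test(group_a, group_b, adjacency,
                             n_perm: int = 10000, p_thresh: float = 1e-4,
                             seed=None, max_masses=None) -> ClusterResult:
    """Spatio-temporal cluster-based permutation test between two groups.

    ``group_a`` and ``group_b`` are (subjects, sensors, samples) arrays of
    disjoint subject groups.  A pooled-variance two-sample t-statistic is
    computed at every (sensor, sample); points exceeding the two-sided
    t-quantile at ``p_thresh`` (df = nA + nB - 2) are grouped into
    spatio-temporally connected clusters of a common sign, whose mass is
    the sum of member t-values.  The null distribution is the maximum
    absolute cluster mass over random relabellings of the subjects, and
    each observed cluster gets ``p = (1 + #{null >= |mass|}) / (1 + n_perm)``.

    Parameters
    ----------
    adjacency : scipy.sparse matrix
        Symmetric boolean sensor neighbourhood (see
        :func:`alphashift.montage.sensor_adjacency`).
    max_masses : ndarray, optional
        Output buffer; when given, the permutation null is written into it
        (length ``n_perm``) for diagnostics.
    """
    xa = np.asarray(group_a, dtype=float)
    xb = np.asarray(group_b, dtype=float)
    if xa.ndim != 3 or xb.ndim != 3 or xa.shape[1:] != xb.shape[1:]:
        raise ValueError("groups must be (subjects, sensors, samples) with "
                         "matching grids")
    na, nb = xa.shape[0], xb.shape[0]
    if min(na, nb) < 2:
        raise ValueError("need at least 2 subjects per group")
    adj = sparse.csr_matrix(adjacency)
    if adj.shape[0] != xa.shape[1]:
        raise ValueError("adjacency does not match the sensor dimension")
    if (adj != adj.T).nnz:
        raise ValueError("adjacency must be symmetric")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)

    n_sensors, n_samples = xa.shape[1:]
    df = na + nb - 2
    threshold = float(t_dist.ppf(1.0 - p_thresh / 2.0, df))
    grid_adj = _grid_adjacency(adj, n_samples)

    x = np.concatenate([xa, xb], axis=0).reshape(na + nb, -1)
    t_obs = _t_two_sample(x[:na], x[na:]).reshape(-1)
    observed = (_clusters_from_mask(t_obs > threshold, t_obs, grid_adj)
                + _clusters_from_mask(t_obs < -threshold, t_obs, grid_adj))

    # permutation null: group sums for blocks of relabellings via matmul
    rng = np.random.default_rng(seed)
    n_tot = na + nb
    x2 = x * x
    s_tot = x.sum(axis=0)
    s2_tot = x2.sum(axis=0)
    null = np.zeros(n_perm)
    block = max(1, min(256, int(2e7 // max(1, x.shape[1]))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(np.arange(n_tot), (b, 1)), axis=1)
        sel = np.zeros((b, n_tot))
        sel[np.arange(b)[:, None], perms[:, :na]] = 1.0
        sa, sa2 = sel @ x, sel @ x2
        ma = sa / na
        mb = (s_tot - sa) / nb
        va = (sa2 - na * ma * ma) / (na - 1)
        vb = ((s2_tot - sa2) - nb * mb * mb) / (nb - 1)
        sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(np.clip(sp, 0.0, None) * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_blk = np.where(denom > 0, (ma - mb) / denom, 0.0)
        for i in range(b):
            t_p = t_blk[i]
            best = 0.0
            for sign_mask in (t_p > threshold, t_p < -threshold):
                for _, mass in _clusters_from_mask(sign_mask, t_p, grid_adj):
                    best = max(best, abs(mass))
            null[done + i] = best
        done += b
    if max_masses is not None:
        max_masses[:] = null

    clusters = []
    for members, mass in observed:
        pval = (1.0 + np.count_nonzero(null >= abs(mass))) / (1.0 + n_perm)
        pts = np.column_stack(np.unravel_index(members, (n_sensors, n_samples)))
        clusters.append(Cluster(pts, mass, float(pval)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(t_obs.reshape(n_sensors, n_samples), clusters,
                         n_perm, threshold, p_thresh)


def cluster_signflip_test(diffs, adjacency, n_perm: int = 10000,
                          p_thresh: float = 1e-4, seed=None) -> ClusterResult:
    """Paired-design variant: one-sample t on per-subject difference maps.

    ``diffs`` is (subjects, sensors, samples); the null distribution flips
    the sign of whole subjects at random, which is exact when the paired
    differences are symmetrically distributed under the null.  Clustering
    and p-values mirror :func:`cluster_permutation_test`.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 3:
        raise ValueError("diffs must be (subjects, sensors, samples)")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    adj = sparse.csr_matrix(adjacency)
    n_sensors, n_samples = d.shape[1:]
    df = n - 1
    threshold = float(t_dist.ppf(1.0 - p_thresh / 2.0, df))
    grid_adj = _grid_adjacency(adj, n_samples)
    x = d.reshape(n, -1)

    def one_sample_t(signs):
        m = signs @ x / n
        v = (x * x).sum(axis=0) / n - m * m     # signs^2 = 1
        v = v * n / (n - 1)
        denom = np.sqrt(np.clip(v, 0.0, None) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, m / denom, 0.0)

    t_obs = one_sample_t(np.ones(n))
    observed = (_clusters_from_mask(t_obs > threshold, t_obs, grid_adj)
                + _clusters_from_mask(t_obs < -threshold, t_obs, grid_adj))
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_p = one_sample_t(signs)
        best = 0.0
        for mask in (t_p > threshold, t_p < -threshold):
            for _, mass in _clusters_from_mask(mask, t_p, grid_adj):
                best = max(best, abs(mass))
        null[p] = best
    clusters = []
    for members, mass in observed:
        pval = (1.0 + np.count_nonzero(null >= abs(mass))) / (1.0 + n_perm)
        pts = np.column_stack(np.unravel_index(members, (n_sensors, n_samples)))
        clusters.append(Cluster(pts, mass, float(pval)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(t_obs.reshape(n_sensors, n_samples), clusters,
                         n_perm, threshold, p_thresh)


# ---------------------------------------------------------------------------
# correlations and contrasts
# ---------------------------------------------------------------------------

def timecourse_correlation(er_data, env_data, fs: float, t_start_s: float,
                           window=(0.0, 1.0), p_base: float = 1e-4):
    """Per-sensor Pearson correlation of evoked and envelope time courses.

    Correlates the two (n_sensors, n_samples) traces over the samples in
    ``window`` and masks significance at the Bonferroni-corrected threshold
    ``p_base / n_sensors``.  Sensors with a constant trace get ``r = nan``
    and are masked out (logged).

    Returns ``(r, p, mask)`` arrays of length n_sensors.
    """
    er = np.asarray(er_data, dtype=float)
    env = np.asarray(env_data, dtype=float)
    if er.shape != env.shape or er.ndim != 2:
        raise ValueError("time courses must share a (sensors, samples) shape")
    t = t_start_s + np.arange(er.shape[1]) / fs
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 3:
        raise ValueError("window too short for a correlation")
    n_sensors = er.shape[0]
    r = np.full(n_sensors, np.nan)
    p = np.ones(n_sensors)
    for s in range(n_sensors):
        a, b = er[s, sel], env[s, sel]
        if a.std() == 0 or b.std() == 0:
            logger.info("constant trace at sensor %d; correlation undefined", s)
            continue
        r[s], p[s] = pearsonr(a, b)
    mask = np.nan_to_num(p, nan=1.0) < (p_base / n_sensors)
    return r, p, mask


def contrast_topographies(er_target, er_standard, env_target, env_standard,
                          peak, fs: float, t_start_s: float,
                          half_window_s: float = 0.05):
    """Target-vs-standard contrast maps at the evoked-response peak.

    ``er_diff`` is the target-minus-standard evoked amplitude sampled at
    the peak latency; ``alpha_ratio`` is the mean envelope in
    ``[t_peak - 50 ms, t_peak + 50 ms]`` after targets divided by the same
    quantity after standards.  All inputs are (n_sensors, n_samples).
    """
    er_t = np.asarray(er_target, dtype=float)
    er_s = np.asarray(er_standard, dtype=float)
    env_t = np.asarray(env_target, dtype=float)
    env_s = np.asarray(env_standard, dtype=float)
    latency = peak.latency_s if hasattr(peak, "latency_s") else float(peak)
    t = t_start_s + np.arange(er_t.shape[1]) / fs
    j = int(np.argmin(np.abs(t - latency)))
    er_diff = er_t[:, j] - er_s[:, j]
    win = (t >= latency - half_window_s) & (t <= latency + half_window_s)
    denom = env_s[:, win].mean(axis=1)
    if np.any(denom <= 0):
        raise ValueError("standard envelope is zero in the peak window")
    alpha_ratio = env_t[:, win].mean(axis=1) / denom
    return er_diff, alpha_ratio


def spearman_topography_similarity(map_a, map_b) -> float:
    """Spearman rank correlation between two per-sensor contrast maps."""
    a = rankdata(np.asarray(map_a, dtype=float))
    b = rankdata(np.asarray(map_b, dtype=float))
    r, _ = pearsonr(a, b)
    return float(r)
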