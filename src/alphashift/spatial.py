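"""Spatial filters: pooled LDA for evoked responses, CSP for alpha power.

A spatial *filter* W is a per-sensor weight vector that extracts a source
as a virtual channel ``w @ x``; the corresponding *pattern*
``a = (C w) / (w' C w)`` (C the data covariance) describes how that source
projects onto the sensors and is the quantity to interpret topographically.

``fit_lda_filter`` trains a two-class shrinkage LDA on per-subject evoked
amplitudes (target vs standard) and returns the discriminant as a filter
with its activation pattern.  ``fit_csp`` jointly diagonalises two class
covariances via a whitened eigendecomposition; eigenvalues are the fraction
of target-class variance captured by each component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

logger = logging.getLogger(__name__)

__all__ = ["SpatialFilter", "fit_lda_filter", "filter_to_pattern",
           "fit_csp", "select_csp_component", "apply_filter"]


class DegenerateFilterError(ValueError):
    """Filter has (numerically) zero variance under the given covariance."""


@dataclass
class SpatialFilter:
    weights: np.ndarray
    pattern: np.ndarray
    method: str                       # "lda" or "csp"
    eigenvalue: float | None = None
    window_s: tuple = (0.3, 0.7)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.pattern = np.asarray(self.pattern, dtype=float).ravel()
        if np.linalg.norm(self.weights) == 0:
            raise ValueError("filter weights are all zero")
        if not np.all(np.isfinite(self.pattern)):
            raise ValueError("pattern contains non-finite values")


def filter_to_pattern(weights: np.ndarray, data_cov: np.ndarray) -> np.ndarray:
    """Activation pattern of a filter: ``a = C w / (w' C w)``.

    The filter is normalised to unit length first, which makes the pattern
    invariant to positive rescaling of ``w``.  Raises
    :class:`DegenerateFilterError` when ``w' C w <= 0``.
    """
    w = np.asarray(weights, dtype=float).ravel()
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DegenerateFilterError("zero filter")
    w = w / norm
    c = np.asarray(data_cov, dtype=float)
    if c.shape != (w.size, w.size):
        raise ValueError("covariance shape does not match the filter")
    if not np.allclose(c, c.T, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise ValueError("covariance must be symmetric")
    denom = float(w @ c @ w)
    if denom <= 0:
        raise DegenerateFilterError("w' C w <= 0: degenerate filter/covariance")
    return (c @ w) / denom


def fit_lda_filter(target_amps: np.ndarray, standard_amps: np.ndarray,
                   window_s=(0.3, 0.7)) -> SpatialFilter:
    """Two-class shrinkage LDA on per-subject evoked amplitudes.

    ``target_amps`` and ``standard_amps`` are (n_subjects, n_sensors)
    matrices of time-window-averaged evoked amplitudes forming the two
    classes.  The discriminant uses the pooled within-class covariance with
    analytic (Ledoit-Wolf) shrinkage, which regularises the small synthetic
    cohorts where the 31-dim covariance would otherwise be ill-conditioned.
    The pattern is derived from the covariance of the stacked data.
    """
    x1 = np.atleast_2d(np.asarray(target_amps, dtype=float))
    x0 = np.atleast_2d(np.asarray(standard_amps, dtype=float))
    if x1.shape[1] != x0.shape[1]:
        raise ValueError("classes must share the sensor dimension")
    if min(x1.shape[0], x0.shape[0]) < 2:
        raise ValueError("need at least 2 subjects per class")
    x = np.vstack([x1, x0])
    y = np.concatenate([np.ones(len(x1)), np.zeros(len(x0))])
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(x, y)
    w = lda.coef_.ravel()
    cov = np.cov(x, rowvar=False)
    return SpatialFilter(w, filter_to_pattern(w, cov), "lda", None, tuple(window_s))


def fit_csp(cov_target: np.ndarray, cov_standard: np.ndarray,
            window_s=(0.3, 0.7)) -> list[SpatialFilter]:
    """Common spatial patterns from two pooled class covariances.

    Solves the generalised eigenproblem ``C_t w = lambda (C_t + C_s) w``
    through a whitening eigendecomposition of the composite covariance
    (numerically stabler than a direct generalised solver).  Rank-deficient
    composites are ridge-regularised with a logged epsilon.  Returns all
    components sorted by descending eigenvalue; filters diagonalise both
    class covariances, and each eigenvalue in [0, 1] is the target-class
    share of the component's variance.
    """
    ct = np.asarray(cov_target, dtype=float)
    cs = np.asarray(cov_standard, dtype=float)
    if ct.shape != cs.shape or ct.ndim != 2 or ct.shape[0] != ct.shape[1]:
        raise ValueError("covariances must be square and of equal dimension")
    for c, name in ((ct, "target"), (cs, "standard")):
        if not np.allclose(c, c.T, atol=1e-8 * max(1.0, np.abs(c).max())):
            raise ValueError(f"{name} covariance is not symmetric")
    comp = ct + cs
    evals, evecs = np.linalg.eigh(comp)
    tol = comp.shape[0] * np.finfo(float).eps * evals.max()
    if evals.min() <= tol:
        eps = 1e-9 * np.trace(comp) / comp.shape[0]
        logger.info("rank-deficient composite covariance; ridge eps=%.3e", eps)
        comp = comp + eps * np.eye(comp.shape[0])
        evals, evecs = np.linalg.eigh(comp)
    whitener = evecs / np.sqrt(evals)          # columns: whitening directions
    s = whitener.T @ ct @ whitener
    s = 0.5 * (s + s.T)
    lam, v = np.linalg.eigh(s)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, 1.0)
    w_all = whitener @ v[:, order]             # columns are filters
    pattern_all = comp @ w_all                 # w' comp w = 1 by construction
    filters = []
    for k in range(w_all.shape[1]):
        filters.append(SpatialFilter(w_all[:, k], pattern_all[:, k], "csp",
                                     float(lam[k]), tuple(window_s)))
    return filters


def select_csp_component(filters: list[SpatialFilter],
                         reference_topography: np.ndarray) -> SpatialFilter:
    """Pick the component whose pattern best matches a reference topography.

    Similarity is absolute cosine similarity between the component pattern
    and the reference (typically the evoked-response contrast topography);
    ties — including a reference orthogonal to every pattern — are broken
    by the larger eigenvalue, with a warning in the degenerate case.
    """
    if not filters:
        raise ValueError("empty filter set")
    ref = np.asarray(reference_topography, dtype=float).ravel()
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise ValueError("reference topography is the zero vector")
    sims = np.array([
        abs(f.pattern @ ref) / (np.linalg.norm(f.pattern) * nref)
        for f in filters])
    best = sims.max()
    if best < 1e-12:
        logger.warning("reference orthogonal to all CSP patterns; "
                       "selecting by eigenvalue only")
    tied = np.flatnonzero(sims >= best - 1e-12)
    evs = np.array([filters[i].eigenvalue or 0.0 for i in tied])
    return filters[tied[np.argmax(evs)]]


def apply_filter(filt: SpatialFilter, data: np.ndarray,
                 sensor_axis: int = -2) -> np.ndarray:
    """Project multichannel data onto the filter's virtual channel.

    Works for (n_sensors, n_samples) evoked arrays and
    (n_trials, n_sensors, n_samples) epochs alike.
    """
    data = np.asarray(data, dtype=float)
    return np.tensordot(filt.weights, data, axes=([0], [sensor_axis % data.ndim]))
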