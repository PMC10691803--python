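"""Cognitive composites, age-adjusted associations, and mediation.

Composite scores follow the usual neuropsychology recipe: impute missing or
implausible raw test values with the sample mean, invert times-to-complete
(1/value, so that larger is better everywhere), z-score each test, and
average the z-scores.  Associations between EEG markers and composites are
ordinary least squares with age as a covariate and the marker standardised
so betas are comparable across markers.  Mediation follows the classical
three-regression decomposition with a nonparametric percentile bootstrap
for uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["RegressionResult", "MediationResult",
           "composite_score", "regress_with_age", "mediate"]


@dataclass
class RegressionResult:
    beta: float
    se: float
    p_value: float
    n: int


@dataclass
class MediationResult:
    """Linear mediation decomposition.

    ``total`` is the x-coefficient in ``y ~ x (+ cov)``; ``indirect`` is
    the product of the x->mediator and mediator->y path coefficients;
    ``direct`` the x-coefficient in the full model.  ``prop_mediated`` is
    ``indirect / total`` and is flagged inconsistent when total and
    indirect disagree in sign (the ratio is then not a proportion).
    """

    total: float
    direct: float
    indirect: float
    prop_mediated: float
    ci_level: float
    indirect_ci: tuple
    prop_mediated_ci: tuple
    n_boot: int
    sign_inconsistent: bool


def composite_score(component_values, invert_flags, impute: str = "mean",
                    implausible_iqr: float = 3.0) -> np.ndarray:
    """Composite cognitive score from raw per-test values.

    Parameters
    ----------
    component_values : (n_subjects, n_tests) array
        Raw test results; times-to-complete in seconds or recall fractions.
    invert_flags : sequence of bool
        Tests to invert (1/value) before z-scoring, i.e. times-to-complete
        where smaller is better.  Inverted tests must be positive;
        non-positive entries are treated as implausible and imputed.
    implausible_iqr : float
        Values farther than this many interquartile ranges from the median
        are treated as implausible and imputed like missing values.
    """
    x = np.array(component_values, dtype=float)
    if x.ndim != 2:
        raise ValueError("component_values must be (n_subjects, n_tests)")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    flags = np.asarray(invert_flags, dtype=bool)
    if flags.shape != (m,):
        raise ValueError("one invert flag per test required")
    if impute != "mean":
        raise ValueError("only mean imputation is supported")
    z = np.empty_like(x)
    for j in range(m):
        col = x[:, j].copy()
        bad = ~np.isfinite(col)
        finite = col[~bad]
        if finite.size:
            q1, med, q3 = np.percentile(finite, [25, 50, 75])
            iqr = q3 - q1
            if iqr > 0:
                bad |= np.abs(col - med) > implausible_iqr * iqr
        if flags[j]:
            bad |= ~np.isfinite(col) | (col <= 0)
        if bad.any():
            logger.info("test %d: imputing %d missing/implausible value(s)",
                        j, int(bad.sum()))
        if bad.all():
            raise ValueError(f"test {j} has no usable values")
        col[bad] = col[~bad].mean()
        if flags[j]:
            col = 1.0 / col
        sd = col.std()
        if sd == 0:
            logger.info("test %d is constant; its z-scores are defined as 0", j)
            z[:, j] = 0.0
        else:
            z[:, j] = (col - col.mean()) / sd
    return z.mean(axis=1)


def regress_with_age(score, predictor, age) -> RegressionResult:
    """OLS of a cognitive score on a standardised marker plus age.

    Returns the marker's coefficient, its standard error, and p-value.
    The marker is z-scored before fitting so betas are comparable across
    markers of different physical units.
    """
    score = np.asarray(score, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (score.shape == predictor.shape == age.shape):
        raise ValueError("score, predictor and age must have equal length")
    n = score.size
    if n <= 3:
        raise ValueError("need n > 3 observations")
    if not (np.isfinite(score).all() and np.isfinite(predictor).all()
            and np.isfinite(age).all()):
        raise ValueError("inputs must be finite")
    if predictor.std() == 0:
        raise ValueError("predictor has zero variance")
    if age.std() > 0:
        r = np.corrcoef(predictor, age)[0, 1]
        if abs(r) > 0.999:
            raise ValueError("predictor and age are collinear")
    zpred = (predictor - predictor.mean()) / predictor.std()
    design = sm.add_constant(np.column_stack([zpred, age]))
    fit = sm.OLS(score, design).fit()
    return RegressionResult(float(fit.params[1]), float(fit.bse[1]),
                            float(fit.pvalues[1]), n)


def _ols_coef(y, cols):
    """First-column coefficient of y on [1, cols...] via lstsq."""
    design = np.column_stack([np.ones(len(y))] + list(cols))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def mediate(x, mediator, y, covariate=None, n_boot: int = 2000,
            seed=None, ci_level: float = 0.95) -> MediationResult:
    """Proportion of an x -> y association mediated by a third variable.

    Three regressions are fitted: the total effect ``y ~ x (+ covariate)``,
    the mediator path ``mediator ~ x``, and the full model
    ``y ~ x + mediator (+ covariate)``.  The indirect effect is the product
    of the x->mediator coefficient and the mediator coefficient of the full
    model; the proportion mediated is indirect/total.  Percentile bootstrap
    confidence intervals (case resampling, seeded) are reported for the
    indirect effect and the proportion.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == y.size == n):
        raise ValueError("x, mediator and y must have equal length")
    if n <= 10:
        raise ValueError("need n > 10 observations")
    if m.std() == 0:
        raise ValueError("mediator has zero variance")
    cov = None if covariate is None else np.asarray(covariate, dtype=float)

    def paths(xi, mi, yi, ci):
        extra = [] if ci is None else [ci]
        total = _ols_coef(yi, [xi] + extra)[1]
        a = _ols_coef(mi, [xi])[1]
        full = _ols_coef(yi, [xi, mi] + extra)
        direct, b = full[1], full[2]
        return total, direct, a * b

    total, direct, indirect = paths(x, m, y, cov)
    prop = indirect / total if total != 0 else np.nan
    rng = np.random.default_rng(seed)
    boots_ind = np.empty(n_boot)
    boots_prop = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ci = None if cov is None else cov[idx]
        try:
            tt, _, ii = paths(x[idx], m[idx], y[idx], ci)
        except np.linalg.LinAlgError:   # pathological resample
            boots_ind[i] = np.nan
            boots_prop[i] = np.nan
            continue
        boots_ind[i] = ii
        boots_prop[i] = ii / tt if tt != 0 else np.nan
    lo = 100 * (1 - ci_level) / 2
    hi = 100 - lo
    ind_ci = tuple(np.nanpercentile(boots_ind, [lo, hi]))
    prop_ci = tuple(np.nanpercentile(boots_prop, [lo, hi]))
    return MediationResult(
        total=float(total), direct=float(direct), indirect=float(indirect),
        prop_mediated=float(prop), ci_level=ci_level,
        indirect_ci=ind_ci, prop_mediated_ci=prop_ci, n_boot=n_boot,
        sign_inconsistent=bool(np.sign(total) != np.sign(indirect)
                               and total != 0 and indirect != 0))
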