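"""Two-step spectral outlier screening.

Step one cleans the calibration library: a PLSR model is fitted on all
samples of a property and its residuals from the 1:1 line are scanned
against a grid of standard-deviation thresholds (0.1–3.0 in steps of
0.02); the smallest threshold whose flagged fraction stays within the
cap (1% by default) is kept, so the screen removes as many samples as
the cap permits.  Screening is run once per property with that
property's model.

Step two guards predictions: new spectra whose squared residual off the
calibration PCA subspace is improbably large relative to the pooled
calibration residuals are flagged by an F-ratio as falling outside the
calibration space.  Flagged samples are annotated as potentially
unreliable, not removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regression import fit_plsr
from .transfer import _n_pc_for_variance, pca_fit, pca_scores

__all__ = [
    "OutlierScreenResult",
    "screen_calibration_outliers",
    "FRatioResult",
    "f_ratio_flags",
]

log = logging.getLogger(__name__)


@dataclass
class OutlierScreenResult:
    """Calibration-screen outcome at the selected SD threshold."""

    chosen_threshold: float
    residual_sd: float
    flags: np.ndarray
    flagged_fraction: float
    residuals: np.ndarray

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.flags)


def screen_calibration_outliers(
    X: np.ndarray,
    y: np.ndarray,
    grid_lo: float = 0.1,
    grid_hi: float = 3.0,
    grid_step: float = 0.02,
    max_fraction: float = 0.01,
    max_ncomp: int = 20,
    seed: int = 0,
) -> OutlierScreenResult:
    """Flag calibration samples far from the 1:1 line of a global PLSR.

    A sample is flagged at threshold ``t`` when
    ``|predicted - observed| > t * SD(residuals)``; the chosen threshold
    is the smallest grid value whose flagged fraction does not exceed
    ``max_fraction``.  If no grid value satisfies the cap the upper grid
    bound is used with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 50:
        raise ValueError("calibration screening requires at least 50 samples")
    model = fit_plsr(X, y, max_ncomp=max_ncomp, seed=seed)
    residuals = model.predict(X) - y
    sd = float(residuals.std(ddof=1))
    if sd <= 1e-10 * float(np.std(y)):
        # numerically perfect fit: nothing exceeds any positive threshold
        return OutlierScreenResult(
            chosen_threshold=float(grid_lo),
            residual_sd=sd,
            flags=np.zeros(y.size, dtype=bool),
            flagged_fraction=0.0,
            residuals=residuals,
        )
    n_steps = int(round((grid_hi - grid_lo) / grid_step))
    grid = grid_lo + grid_step * np.arange(n_steps + 1)
    abs_res = np.abs(residuals)
    chosen = None
    for t in grid:
        frac = float(np.mean(abs_res > t * sd))
        if frac <= max_fraction:
            chosen = float(t)
            break
    if chosen is None:
        chosen = float(grid[-1])
        log.warning(
            "no SD threshold in [%g, %g] meets the %.1f%% cap; using %g",
            grid_lo,
            grid_hi,
            100 * max_fraction,
            chosen,
        )
    flags = abs_res > chosen * sd
    return OutlierScreenResult(
        chosen_threshold=chosen,
        residual_sd=sd,
        flags=flags,
        flagged_fraction=float(flags.mean()),
        residuals=residuals,
    )


@dataclass
class FRatioResult:
    """Per-sample F statistics and outlier flags for a prediction set."""

    statistic: np.ndarray
    p_value: np.ndarray
    flags: np.ndarray
    pca_rank_used: int


def f_ratio_flags(
    X_cal: np.ndarray,
    X_new: np.ndarray,
    p_cutoff: float = 0.99,
    variance_target: float = 0.995,
) -> FRatioResult:
    """Flag prediction spectra outside the calibration space.

    A PCA is fitted on the calibration spectra with the rank explaining
    at least ``variance_target`` of the variance.  For a new spectrum
    with squared off-subspace residual ``q``, the statistic is

        F = q * (n_cal - 1) / sum(q_cal)

    and the sample is flagged when the F(1, n_cal - 1) CDF at its
    statistic exceeds ``p_cutoff``.  The reference distribution treats
    the residual as one dominant mode pooled against the calibration
    residuals; with broadband uncorrelated channel noise the statistic
    concentrates and the screen is conservative.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    n_cal = X_cal.shape[0]
    if n_cal < 30:
        raise ValueError("F-ratio screening requires at least 30 calibration samples")
    rank = _n_pc_for_variance(X_cal, variance_target, min(n_cal - 1, X_cal.shape[1]))
    model = pca_fit(X_cal, rank)

    def sq_residual(X):
        centered = X - model.center
        recon = pca_scores(model, X) @ model.loadings.T
        return np.sum((centered - recon) ** 2, axis=1)

    q_cal = sq_residual(X_cal)
    q_new = sq_residual(X_new)
    pooled = float(q_cal.sum())
    total = float(np.sum((X_cal - X_cal.mean(axis=0)) ** 2))
    if pooled <= 1e-12 * max(total, 1e-30):
        log.info("zero calibration residual variance; nothing flagged")
        stat = np.zeros(X_new.shape[0])
        pv = np.zeros(X_new.shape[0])
    else:
        stat = q_new * (n_cal - 1) / pooled
        pv = stats.f.cdf(stat, 1, n_cal - 1)
    flags = pv > p_cutoff
    return FRatioResult(statistic=stat, p_value=pv, flags=flags, pca_rank_used=rank)
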