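"""Robust rejection of centroid-residual outliers before minimization.

Least squares is neither robust nor resistant, so gross outliers among the
(X, Y, phi) residuals are identified and removed once, before the target is
minimized.  Two rules are offered: a per-coordinate box-plot (Tukey fences)
rule whose acceptance region is a cuboid, and a multivariate rule that flags
points by squared Mahalanobis distance from a robust location/covariance
estimate (the minimum covariance determinant), whose acceptance region is an
ellipsoid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet

logger = logging.getLogger(__name__)

__all__ = ["McdEstimate", "tukey_outliers", "fast_mcd", "mahalanobis_outliers", "sauter_poon"]


@dataclass
class McdEstimate:
    """Robust location and scatter from the minimum covariance determinant."""

    location: np.ndarray
    covariance: np.ndarray
    support_size: int
    consistency_corrected: bool = True


def tukey_outliers(residuals: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Box-plot rejection: outside [Q1 - m*IQR, Q3 + m*IQR] in any coordinate.

    ``residuals`` is (n, k); with the default multiplier 1.5 the fences are
    Tukey's inner fences.  Returns a boolean outlier mask of length n.  A
    zero-IQR coordinate degenerates to flagging every value away from the
    median (with a warning).
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if residuals.shape[0] < 4:
        raise ValueError("need at least 4 points per coordinate for quartiles")
    mask = np.zeros(residuals.shape[0], dtype=bool)
    for j in range(residuals.shape[1]):
        col = residuals[:, j]
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            logger.warning("zero IQR in residual coordinate %d; flagging values off the median", j)
            mask |= col != np.median(col)
            continue
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        mask |= (col < lo) | (col > hi)
    return mask


def fast_mcd(points: np.ndarray, alpha: float | None = None, seed: int = 0) -> McdEstimate:
    """Minimum covariance determinant estimate of location and scatter.

    Runs the FAST-MCD algorithm (random elemental subsets refined by
    concentration steps, keeping the subset of size h with the smallest
    covariance determinant) with consistency and small-sample corrections so
    the covariance is unbiased for normal data.  The default support is
    h = floor((n + dim + 1) / 2); pass ``alpha`` = h/n to change it.
    Deterministic given ``seed``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = points.shape
    if n < 10:
        raise ValueError("need at least 10 points for a stable MCD estimate")
    support_fraction = alpha
    mcd = MinCovDet(support_fraction=support_fraction, random_state=int(seed) % (2**31)).fit(points)
    cov = mcd.covariance_
    if np.linalg.matrix_rank(cov) < d:
        raise ValueError("degenerate MCD support: singular covariance")
    return McdEstimate(
        location=mcd.location_,
        covariance=cov,
        support_size=int(mcd.support_.sum()),
    )


def mahalanobis_outliers(
    residuals: np.ndarray, level: float = 0.975, estimate: McdEstimate | None = None, seed: int = 0
) -> np.ndarray:
    """Flag points whose squared Mahalanobis distance exceeds the chi-squared quantile.

    For k-variate normal residuals the squared distances follow a chi-squared
    distribution with k degrees of freedom (k = 3 for rotation data); the
    default cutoff is its 97.5% quantile.  If no robust estimate is supplied
    one is computed with :func:`fast_mcd`.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if estimate is None:
        estimate = fast_mcd(residuals, seed=seed)
    delta = residuals - estimate.location
    d2 = np.sum(delta @ np.linalg.inv(estimate.covariance) * delta, axis=1)
    cutoff = stats.chi2.ppf(level, df=residuals.shape[1])
    return d2 > cutoff


def sauter_poon(*args, **kwargs):
    """Detector-plane-only outlier rejection; recognised but not provided here."""
    raise NotImplementedError(
        "the (X, Y)-only outlier method is not implemented; use 'tukey' or 'mcd'"
    )
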