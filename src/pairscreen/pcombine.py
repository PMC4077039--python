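"""Combine the two directional p-values of each pair into one ranking score.

Every pair (A, B) receives two p-values: one from the distribution of all
A-perturbations at fixed B, one from the distribution of all B-perturbations
at fixed A.  Both are computed from the same underlying measurements and are
therefore dependent.  Three combiners are provided:

``mean``
    Arithmetic mean.  Strongly penalizes pairs where only one direction is
    significant (a pair with p = 1e-9 and p = 1 combines to ~0.5).
``product``
    The product, a ranking score rather than a calibrated probability; the
    most aggressive of the three.
``brown``
    Brown's method, Fisher's chi-square combination corrected for the
    dependence between the two p-values.  The statistic
    ``X = -2 (ln p_a + ln p_b)`` has mean 4 under the null; its variance is
    inflated from Fisher's 8 by twice the covariance of ``-2 ln p_a`` and
    ``-2 ln p_b``, estimated empirically across all pairs of the screen.
    X / c is referred to a chi-square with f degrees of freedom where
    ``c = var / (2 mean)`` and ``f = 2 mean^2 / var``.  At independence this
    reduces exactly to Fisher's method; at perfect dependence (p_a = p_b)
    it reduces to the identity map.  Brown is the default: a conservative
    middle ground between mean and product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BrownCalibration",
    "combine_mean",
    "combine_product",
    "brown_calibrate",
    "combine_brown",
    "combine",
]

#: E[-2 ln p] = 2 per uniform p-value, so the two-value sum has mean 4.
_MEAN_STAT = 4.0
#: Var[-2 ln p] = 4 per independent uniform p-value.
_VAR_INDEP = 8.0


@dataclass(frozen=True)
class BrownCalibration:
    """Scaled chi-square reference for the dependent Fisher statistic.

    Attributes
    ----------
    mean_stat : float
        Expected value of X = -2(ln p_a + ln p_b); pinned at the
        theoretical 4 so a hit-rich screen does not deflate its own
        significance.
    var_stat : float
        8 + 2 cov(-2 ln p_a, -2 ln p_b), with the covariance clipped to
        [0, 4]; hence var_stat in [8, 16].
    scale_c : float
        var_stat / (2 mean_stat).
    dof_f : float
        2 mean_stat^2 / var_stat, in [2, 4].
    n_pairs : int
        Number of complete (p_a, p_b) pairs the covariance was estimated on.
    """

    mean_stat: float
    var_stat: float
    scale_c: float
    dof_f: float
    n_pairs: int = 0


def _asarray_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(p) & ((p <= 0) | (p > 1))
    if bad.any():
        raise ValueError("p-values must lie in (0, 1]")
    return p


def combine_mean(p_a, p_b):
    """Arithmetic mean of the two p-values; missing input gives missing output."""
    p_a, p_b = _asarray_p(p_a), _asarray_p(p_b)
    return (p_a + p_b) / 2.0


def combine_product(p_a, p_b):
    """Product of the two p-values (a ranking score, not a probability)."""
    p_a, p_b = _asarray_p(p_a), _asarray_p(p_b)
    return p_a * p_b


def brown_calibrate(p_a, p_b, min_pairs: int = 30) -> BrownCalibration:
    """Estimate the dependence-corrected chi-square reference from a screen.

    Parameters
    ----------
    p_a, p_b : array-like
        Directional p-values of all pairs in the result set; pairs with a
        missing value are ignored for calibration.
    min_pairs : int
        Below this number of complete pairs the empirical covariance is
        unreliable; the calibration falls back to independence (Fisher)
        with a warning.
    """
    p_a, p_b = _asarray_p(p_a), _asarray_p(p_b)
    ok = ~(np.isnan(p_a) | np.isnan(p_b))
    xa = -2.0 * np.log(p_a[ok])
    xb = -2.0 * np.log(p_b[ok])
    n = int(ok.sum())
    if n < min_pairs:
        warnings.warn(
            f"only {n} complete p-value pairs (< {min_pairs}); "
            "assuming independence (Fisher's method)",
            stacklevel=2,
        )
        cov = 0.0
    else:
        # variances of -2 ln p are pinned at their null value 4 (like the
        # mean), so only the correlation is taken from the data; perfect
        # dependence then yields cov = 4 exactly rather than a sample
        # variance that merely fluctuates around it
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(xa, xb)[0, 1])
        cov = 4.0 * r if np.isfinite(r) else 0.0
    # negative dependence would be anti-conservative; cov of two chi2_2
    # variables cannot exceed 4
    cov = float(np.clip(cov, 0.0, 4.0))
    var_stat = _VAR_INDEP + 2.0 * cov
    scale_c = var_stat / (2.0 * _MEAN_STAT)
    dof_f = 2.0 * _MEAN_STAT**2 / var_stat
    return BrownCalibration(_MEAN_STAT, var_stat, scale_c, dof_f, n)


def combine_brown(p_a, p_b, calibration: BrownCalibration):
    """Brown-combined p-value(s) under a calibration from the same screen."""
    p_a, p_b = _asarray_p(p_a), _asarray_p(p_b)
    x = -2.0 * (np.log(p_a) + np.log(p_b))
    return stats.chi2.sf(x / calibration.scale_c, calibration.dof_f)


def combine(p_a, p_b, method: str = "brown"):
    """Combine directional p-values by ``brown`` (default), ``mean`` or ``product``.

    For ``brown`` the calibration is estimated from the supplied arrays
    themselves, so the inputs should be the full screen's p-value cloud.
    """
    if method == "mean":
        return combine_mean(p_a, p_b)
    if method == "product":
        return combine_product(p_a, p_b)
    if method == "brown":
        cal = brown_calibrate(p_a, p_b)
        return combine_brown(p_a, p_b, cal)
    raise ValueError(f"unknown combination method {method!r}")
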