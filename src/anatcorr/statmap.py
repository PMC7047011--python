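"""Voxelwise Pearson correlation maps and conversions between statistic scales.

The analysis variable at each voxel is its per-subject series of image values
(e.g. Jacobian determinants from deformable registration), correlated against
one scalar covariate per subject. Downstream corrections treat |r| as the base statistic
because both correlation signs are of interest; the Fisher transform
``z = atanh(r)·sqrt(n-3)`` provides the Gaussianized maps that random-field
corrections require.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from ._util import center_normalize_rows, normalize_vector
from .datatypes import CovariateVector, StatMap

__all__ = [
    "voxelwise_correlation",
    "statistic_to_p",
    "p_to_statistic_threshold",
    "fisher_z",
    "StatMap",
    "CovariateVector",
]

logger = logging.getLogger(__name__)


def voxelwise_correlation(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Pearson correlation between every voxel's subject series and a covariate.

    Parameters
    ----------
    stack:
        4D array, subject axis last; the subject order must match the
        covariate order.
    covariate:
        Per-subject scalar values (length = number of subjects, >= 3).
    mask:
        Optional 3D boolean analysis mask; defaults to all voxels.

    Voxels with a constant subject series have no defined correlation; they
    are removed from the returned map's mask (with a logged count) rather than
    silently set to zero, so max-type statistics are not biased.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must be 4D with the subject axis last")
    cvals = covariate.values if isinstance(covariate, CovariateVector) else np.asarray(covariate, float)
    n = stack.shape[-1]
    if cvals.size != n:
        raise ValueError("covariate length does not match the stack's subject axis")
    if n < 3:
        raise ValueError("at least 3 subjects are required for correlation")
    if np.ptp(cvals) == 0:
        raise ValueError("degenerate covariate: constant across subjects")
    if mask is None:
        mask = np.ones(stack.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[:3]:
        raise ValueError("mask shape does not match the stack grid")

    X = stack[mask]  # (V, n)
    Xn, valid = center_normalize_rows(X)
    c = normalize_vector(cvals)
    r = Xn @ c
    # numerical safety: |r| can exceed 1 by ~1e-16
    np.clip(r, -1.0, 1.0, out=r)

    out_mask = mask.copy()
    if not valid.all():
        n_bad = int((~valid).sum())
        logger.warning("removing %d voxels with constant subject series from the mask", n_bad)
        idx = np.flatnonzero(mask.ravel())
        bad = idx[~valid]
        out_mask.ravel()[bad] = False
        r = r[valid]

    values = np.zeros(stack.shape[:3], dtype=float)
    values[out_mask] = r
    return StatMap(values=values, scale="r", mask=out_mask, n=n)


def _r_to_t(r: np.ndarray, n: int) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    t[np.abs(r) >= 1.0] = np.inf * np.sign(r[np.abs(r) >= 1.0])
    return t


def statistic_to_p(statmap: StatMap, two_sided: bool = True) -> StatMap:
    """Convert an r-scale map to p-values via the exact t transform.

    ``t = r·sqrt((n-2)/(1-r^2))`` with ``n-2`` degrees of freedom; two-sided
    doubles the tail. ``|r| = 1`` maps to the smallest positive float (the t
    statistic is infinite) and a warning is logged.
    """
    if statmap.scale != "r":
        raise ValueError("statistic_to_p expects an r-scale map")
    n = statmap.n
    if n < 3:
        raise ValueError("p conversion needs n >= 3")
    r = statmap.values[statmap.mask]
    t = _r_to_t(r, n)
    df = n - 2
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    exact = ~np.isfinite(t)
    if exact.any():
        logger.warning("%d voxels with |r| = 1 mapped to the smallest positive p", int(exact.sum()))
    p = np.maximum(p, np.finfo(float).tiny)
    values = np.ones(statmap.values.shape, dtype=float)
    values[statmap.mask] = p
    return StatMap(values=values, scale="p", mask=statmap.mask, n=n)


def p_to_statistic_threshold(p: float, n: int, two_sided: bool = True) -> float:
    """The |r| whose (two-sided) p equals ``p`` at sample size ``n``.

    Used to turn a primary (cluster-defining) p threshold such as 0.001 into
    a correlation threshold for forming supra-threshold clusters.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if n < 3:
        raise ValueError("threshold conversion needs n >= 3")
    df = n - 2
    t = stats.t.isf(p / 2.0 if two_sided else p, df)
    t = max(t, 0.0)
    return float(t / np.sqrt(df + t * t))


def fisher_z(statmap: StatMap) -> StatMap:
    """Fisher transform ``z = atanh(r)·sqrt(n-3)``: approximately standard
    normal under the null, the Gaussianized field used by the RFT route."""
    if statmap.scale != "r":
        raise ValueError("fisher_z expects an r-scale map")
    if statmap.n < 4:
        raise ValueError("Fisher z needs n >= 4")
    r = np.clip(statmap.values[statmap.mask], -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r) * np.sqrt(statmap.n - 3)
    values = np.zeros(statmap.values.shape, dtype=float)
    values[statmap.mask] = z
    return StatMap(values=values, scale="z", mask=statmap.mask, n=statmap.n)
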