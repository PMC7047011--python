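"""Parametric FWER corrections: Bonferroni, Holm, and stationary-field RFT.

The random-field route operates on Gaussianized (Fisher-z) correlation maps
and uses the expected Euler characteristic of the thresholded field, with
resel counts derived from a residual-based smoothness estimate. It
deliberately reproduces the vanilla stationary-Gaussian procedure — including
its known fragility when smoothness or stationarity assumptions fail on
anisotropic whole-body data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats
from statsmodels.stats.multitest import multipletests

from ._util import binary_structure
from .datatypes import CorrectionResult, StatMap

__all__ = [
    "SmoothnessEstimate",
    "bonferroni_adjust",
    "holm_adjust",
    "estimate_smoothness",
    "expected_ec",
    "rft_z_threshold",
    "rft_voxel_correct",
    "rft_cluster_correct",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclass
class SmoothnessEstimate:
    """Estimated field smoothness: per-axis FWHM (mm) and the resel count of
    the search region (mask volume divided by the FWHM product)."""

    fwhm: tuple[float, float, float]
    resel_count: float
    # bounding-box side lengths of the mask in resel units, for the lower-order
    # Euler-characteristic terms
    box_resels: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm):
            raise ValueError("FWHM components must be positive")
        if self.resel_count <= 0:
            raise ValueError("resel_count must be positive")


def bonferroni_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m·p)``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if m < p.size:
        raise ValueError("m must be at least the number of supplied p-values")
    return np.minimum(1.0, m * p)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (uniformly dominates Bonferroni)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def estimate_smoothness(
    residual_stack: np.ndarray,
    mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SmoothnessEstimate:
    """Estimate per-axis FWHM from normalized residual spatial derivatives.

    Residual series are standardized voxelwise; the variance of their
    finite differences along each axis gives
    ``FWHM_axis = voxel_size_axis · sqrt(4·ln2 / var(diff))``
    (the standard normalized-residual derivative-variance estimator).
    """
    residual_stack = np.asarray(residual_stack, dtype=float)
    if residual_stack.ndim != 4 or residual_stack.shape[-1] < 2:
        raise ValueError("need a 4D stack of >= 2 residual volumes")
    mask = np.asarray(mask, dtype=bool)
    sd = residual_stack.std(axis=-1)
    valid = mask & (sd > 0)
    if not valid.any():
        raise ValueError("degenerate field: residuals are constant everywhere in the mask")
    U = np.zeros_like(residual_stack)
    U[valid] = (
        residual_stack[valid] - residual_stack[valid].mean(axis=-1, keepdims=True)
    ) / sd[valid][:, None]

    fwhm = []
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        pair = valid[tuple(sl_hi)] & valid[tuple(sl_lo)]
        if not pair.any():
            raise ValueError(f"mask too thin along axis {ax} for smoothness estimation")
        d = U[tuple(sl_hi)][pair] - U[tuple(sl_lo)][pair]
        var = float(np.mean(d * d))
        if var <= 0:
            raise ValueError("degenerate field: zero derivative variance")
        fwhm.append(voxel_size[ax] * np.sqrt(_4LN2 / var))

    vol_mm3 = float(valid.sum()) * float(np.prod(voxel_size))
    resel_count = vol_mm3 / float(np.prod(fwhm))
    # bounding box of the mask, in resels, for the lower-order EC terms
    idx = np.argwhere(valid)
    extent_mm = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(voxel_size)
    box = tuple(float(e / f) for e, f in zip(extent_mm, fwhm))
    return SmoothnessEstimate(tuple(float(f) for f in fwhm), resel_count, box)


def _ec_densities(u: np.ndarray) -> np.ndarray:
    """Gaussian-field EC densities rho_0..rho_3 at threshold u."""
    u = np.asarray(u, dtype=float)
    phi = np.exp(-0.5 * u * u)
    rho0 = stats.norm.sf(u)
    rho1 = np.sqrt(_4LN2) / (2.0 * np.pi) * phi
    rho2 = _4LN2 / (2.0 * np.pi) ** 1.5 * u * phi
    rho3 = _4LN2**1.5 / (2.0 * np.pi) ** 2 * (u * u - 1.0) * phi
    return np.stack([rho0, rho1, rho2, rho3])


def _resel_vector(smooth: SmoothnessEstimate) -> np.ndarray:
    a, b, c = smooth.box_resels if any(smooth.box_resels) else (smooth.resel_count ** (1 / 3),) * 3
    return np.array([1.0, a + b + c, a * b + a * c + b * c, smooth.resel_count])


def expected_ec(u: float | np.ndarray, smooth: SmoothnessEstimate) -> float | np.ndarray:
    """Expected Euler characteristic of the field thresholded at u."""
    R = _resel_vector(smooth)
    return R @ _ec_densities(u)


def rft_z_threshold(alpha: float, smooth: SmoothnessEstimate, two_sided: bool = True) -> float:
    """The z threshold at which the expected EC equals alpha (alpha/2 per tail
    when two-sided); the largest root is returned."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    target = alpha / 2.0 if two_sided else alpha
    f = lambda u: expected_ec(u, smooth) - target
    grid = np.linspace(40.0, 0.0, 2001)
    vals = f(grid)
    # scan from the far tail (E[EC] ~ 0 < target) to the first sign change
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("no EC threshold found: search region too small for this alpha")
    i = sign_change[0]
    return float(optimize.brentq(f, grid[i + 1], grid[i], xtol=1e-12, rtol=1e-15))


def rft_voxel_correct(
    zmap: StatMap,
    smooth: SmoothnessEstimate,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> CorrectionResult:
    """Voxel-level RFT correction of a Gaussianized map.

    Adjusted p per voxel is the expected EC at its |z| (doubled when
    two-sided), capped at 1; significance means |z| above the EC threshold.
    """
    if zmap.scale != "z":
        raise ValueError("rft_voxel_correct expects a z-scale map")
    u = rft_z_threshold(alpha, smooth, two_sided)
    z = np.abs(zmap.values[zmap.mask]) if two_sided else zmap.values[zmap.mask]
    adj = np.asarray(expected_ec(np.maximum(z, 0.0), smooth), dtype=float)
    if two_sided:
        adj = 2.0 * adj
    adj = np.clip(adj, np.finfo(float).tiny, 1.0)
    sig = np.zeros(zmap.mask.shape, dtype=bool)
    sig[zmap.mask] = z >= u
    return CorrectionResult(
        level="voxel", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="rft-voxel", mask=zmap.mask,
        params={"threshold_z": u, "two_sided": two_sided, "fwhm": smooth.fwhm,
                "resel_count": smooth.resel_count},
    )


def rft_cluster_correct(
    zmap: StatMap,
    primary_z: float,
    smooth: SmoothnessEstimate,
    alpha: float = 0.05,
    connectivity: int = 26,
    two_sided: bool = True,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CorrectionResult:
    """Cluster-extent RFT correction under the stationary Gaussian model.

    Supra-threshold clusters of |z| >= primary_z get the classical
    extent p-value ``1 - exp(-E[m]·P(n >= k))`` with
    ``P(n >= k) = exp(-beta·k^(2/3))``; E[m] is the expected cluster count at
    the primary threshold (doubled for two tails).
    """
    if zmap.scale != "z":
        raise ValueError("rft_cluster_correct expects a z-scale map")
    if primary_z <= 0:
        raise ValueError("primary_z must be positive")
    field = np.abs(zmap.values) if two_sided else zmap.values
    sup = (field >= primary_z) & zmap.mask
    lab, n_clusters = ndimage.label(sup, structure=binary_structure(connectivity))

    n_mask = int(zmap.mask.sum())
    e_m = float(expected_ec(primary_z, smooth))
    e_m = max(e_m, np.finfo(float).tiny)
    tail = stats.norm.sf(primary_z)
    if two_sided:
        e_m *= 2.0
        tail *= 2.0
    e_n = n_mask * tail  # expected supra-threshold voxel count
    n_bar = max(e_n / e_m, np.finfo(float).tiny)
    beta = (math.gamma(2.5) / n_bar) ** (2.0 / 3.0)

    if n_clusters == 0:
        return CorrectionResult(
            level="cluster", adjusted_p=np.empty(0), sig_mask=np.zeros_like(sup),
            alpha=alpha, method="rft-cluster", mask=zmap.mask,
            params={"primary_z": primary_z, "n_clusters": 0, "two_sided": two_sided},
        )

    extents = np.bincount(lab.ravel())[1:]
    p_ext = 1.0 - np.exp(-e_m * np.exp(-beta * extents ** (2.0 / 3.0)))
    p_ext = np.clip(p_ext, np.finfo(float).tiny, 1.0)
    sig_clusters = np.nonzero(p_ext <= alpha)[0] + 1
    sig = np.isin(lab, sig_clusters)
    return CorrectionResult(
        level="cluster", adjusted_p=p_ext, sig_mask=sig, alpha=alpha,
        method="rft-cluster", mask=zmap.mask,
        params={"primary_z": primary_z, "n_clusters": int(n_clusters),
                "extents": extents.tolist(), "two_sided": two_sided},
        unit_info={"unit_labels": lab},
    )


def cluster_extent_p(extent: int, primary_z: float, smooth: SmoothnessEstimate,
                     n_mask: int, two_sided: bool = True) -> float:
    """Corrected p for a single cluster extent under the RFT extent model
    (p = 1 for extent <= 0)."""
    if extent <= 0:
        return 1.0
    e_m = max(float(expected_ec(primary_z, smooth)), np.finfo(float).tiny)
    tail = stats.norm.sf(primary_z)
    if two_sided:
        e_m *= 2.0
        tail *= 2.0
    n_bar = max(n_mask * tail / e_m, np.finfo(float).tiny)
    beta = (math.gamma(2.5) / n_bar) ** (2.0 / 3.0)
    p = 1.0 - np.exp(-e_m * np.exp(-beta * extent ** (2.0 / 3.0)))
    return float(np.clip(p, np.finfo(float).tiny, 1.0))
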