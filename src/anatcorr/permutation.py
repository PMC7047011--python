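"""Permutation max-statistic FWER corrections.

The permutation action shuffles the covariate across subjects (the cheapest
action equivalent to permuting subjects for a correlation analysis). For each
permutation the voxelwise correlation map is recomputed and a max-type
statistic recorded; the empirical distribution of those maxima yields
FWER-corrected p-values as #{null >= observed} / n_perm. The identity
permutation is always included, so no corrected p can fall below 1/n_perm and
validity holds by construction.

Implemented statistics: max |r| (voxel level), k-th largest |r| (k-FWER), max
supra-threshold cluster extent, and max TFCE score.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import binary_structure, center_normalize_rows, normalize_vector, substream
from .datatypes import CorrectionResult, CovariateVector, StatMap
from .statmap import p_to_statistic_threshold

__all__ = [
    "PermutationScheme",
    "NullDistribution",
    "TFCEParams",
    "generate_permutations",
    "permutation_p",
    "CorrelationPermutationEngine",
    "voxel_fwer_correct",
    "kmax_fwer_correct",
    "cluster_extent_correct",
    "tfce_transform",
    "tfce_fwer_correct",
]

#: refuse exhaustive enumeration beyond this many permutations
EXHAUSTIVE_CAP = 50_000

#: relative tolerance used when comparing map values against TFCE thresholds,
#: so that a voxel of height h is included at the threshold t == h despite
#: floating-point accumulation in t = k*dt
_TFCE_TOL = 1e-9


@dataclass
class PermutationScheme:
    """A fixed set of subject-index orderings; the first is the identity."""

    permutations: np.ndarray  # (n_perm, n_subjects) integer orderings
    seed: int
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.permutations = np.asarray(self.permutations, dtype=np.intp)
        if self.permutations.ndim != 2:
            raise ValueError("permutations must be a 2D array")
        ident = np.arange(self.permutations.shape[1])
        if not np.array_equal(self.permutations[0], ident):
            raise ValueError("the first permutation must be the identity")

    @property
    def n_perm(self) -> int:
        return int(self.permutations.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.permutations.shape[1])


@dataclass
class NullDistribution:
    """Empirical permutation distribution of a max-type statistic (one value
    per permutation, the first belonging to the identity)."""

    values: np.ndarray
    statistic_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("a null distribution needs at least one value")

    @property
    def n_perm(self) -> int:
        return int(self.values.size)


@dataclass
class TFCEParams:
    """TFCE parameters: height exponent H, extent exponent E, integration step
    dt, and lower integration bound t0 (upper bound is the map maximum)."""

    H: float = 2.0
    E: float = 0.5
    dt: float = 0.1
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be nonnegative")


def generate_permutations(
    n_subjects: int,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermutationScheme:
    """Build a permutation scheme with the identity first.

    Random schemes draw the remaining orderings i.i.d. uniformly; exhaustive
    schemes enumerate all ``n_subjects!`` orderings (refused above
    ``EXHAUSTIVE_CAP`` — use a random scheme instead).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if exhaustive:
        total = math.factorial(n_subjects)
        if total > EXHAUSTIVE_CAP:
            raise ValueError(
                f"{n_subjects}! = {total} exceeds the exhaustive cap of {EXHAUSTIVE_CAP}; "
                "use a random scheme with n_perm draws instead"
            )
        perms = np.array(list(itertools.permutations(range(n_subjects))), dtype=np.intp)
        return PermutationScheme(perms, seed=seed, exhaustive=True)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = substream(seed, "permutations")
    perms = np.empty((n_perm, n_subjects), dtype=np.intp)
    perms[0] = np.arange(n_subjects)
    for i in range(1, n_perm):
        perms[i] = rng.permutation(n_subjects)
    return PermutationScheme(perms, seed=seed, exhaustive=False)


def permutation_p(observed: float, null: NullDistribution | np.ndarray) -> float:
    """Corrected p = #{null values >= observed} / n_perm.

    With the identity permutation included in the null, p >= 1/n_perm.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, float)
    if values.size == 0:
        raise ValueError("empty null distribution")
    return float(np.count_nonzero(values >= observed)) / values.size


class CorrelationPermutationEngine:
    """Recomputes the voxelwise |r| map for arbitrary covariate orderings.

    Voxel series are centered and normalized once; each permutation is then a
    single matrix-vector product. Voxels with constant series are dropped from
    the mask (mirroring :func:`anatcorr.statmap.voxelwise_correlation`).
    """

    def __init__(self, stack: np.ndarray, covariate: CovariateVector | np.ndarray,
                 mask: np.ndarray | None = None):
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 4:
            raise ValueError("stack must be 4D with the subject axis last")
        cvals = covariate.values if isinstance(covariate, CovariateVector) else np.asarray(covariate, float)
        if cvals.size != stack.shape[-1]:
            raise ValueError("covariate length does not match the stack's subject axis")
        if stack.shape[-1] < 3:
            raise ValueError("at least 3 subjects are required")
        if np.ptp(cvals) == 0:
            raise ValueError("degenerate covariate: constant across subjects")
        if mask is None:
            mask = np.ones(stack.shape[:3], dtype=bool)
        mask = np.asarray(mask, dtype=bool)

        Xn, valid = center_normalize_rows(stack[mask])
        self.mask = mask.copy()
        if not valid.all():
            idx = np.flatnonzero(mask.ravel())
            self.mask.ravel()[idx[~valid]] = False
            Xn = Xn[valid]
        if Xn.shape[0] == 0:
            raise ValueError("no voxels with nonconstant series inside the mask")
        self.Xn = Xn
        self.c = normalize_vector(cvals)
        self.n_subjects = int(cvals.size)
        self.shape = stack.shape[:3]

    @property
    def n_voxels(self) -> int:
        return int(self.Xn.shape[0])

    def rvec(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Signed r per masked voxel for one covariate ordering."""
        c = self.c if perm is None else self.c[perm]
        r = self.Xn @ c
        np.clip(r, -1.0, 1.0, out=r)
        return r

    def rvolume(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Signed r as a 3D volume, zero outside the mask."""
        vol = np.zeros(self.shape, dtype=float)
        vol[self.mask] = self.rvec(perm)
        return vol

    def statmap(self) -> StatMap:
        return StatMap(values=self.rvolume(), scale="r", mask=self.mask, n=self.n_subjects)


def voxel_fwer_correct(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    mask: np.ndarray | None,
    scheme: PermutationScheme,
    alpha: float = 0.05,
) -> CorrectionResult:
    """Single-step max-|r| permutation correction at the voxel level."""
    eng = CorrelationPermutationEngine(stack, covariate, mask)
    null = np.empty(scheme.n_perm)
    for i, perm in enumerate(scheme.permutations):
        null[i] = np.abs(eng.rvec(perm)).max()
    obs = np.abs(eng.rvec())
    # corrected p per voxel: rank of its |r| in the max-|r| null
    adj = _batch_permutation_p(obs, null)
    sig = np.zeros(eng.mask.shape, dtype=bool)
    sig[eng.mask] = adj <= alpha
    return CorrectionResult(
        level="voxel", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="perm-voxel", mask=eng.mask,
        params={"n_perm": scheme.n_perm, "seed": scheme.seed},
        unit_info={"null": NullDistribution(null, "max_abs_voxel")},
    )


def kmax_fwer_correct(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    mask: np.ndarray | None,
    scheme: PermutationScheme,
    k: int = 1,
    alpha: float = 0.05,
) -> CorrectionResult:
    """k-FWER correction via the permutation null of the k-th largest |r|.

    ``k = 1`` reduces to the ordinary max-statistic correction; anatomical
    knowledge can bound k by (a fraction of) the smallest organ extent so that
    up to k-1 false voxels never obscure a per-organ inference.
    """
    eng = CorrelationPermutationEngine(stack, covariate, mask)
    V = eng.n_voxels
    if not 1 <= k <= V:
        raise ValueError(f"k must lie in [1, {V}]")
    null = np.empty(scheme.n_perm)
    for i, perm in enumerate(scheme.permutations):
        a = np.abs(eng.rvec(perm))
        null[i] = np.partition(a, V - k)[V - k]
    obs = np.abs(eng.rvec())
    # unlike the max statistic (k=1), a voxel can exceed every permutation's
    # k-th largest value; floor at 1/n_perm to keep p-values valid
    adj = np.maximum(_batch_permutation_p(obs, null), 1.0 / scheme.n_perm)
    sig = np.zeros(eng.mask.shape, dtype=bool)
    sig[eng.mask] = adj <= alpha
    return CorrectionResult(
        level="voxel", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="perm-kmax", mask=eng.mask,
        params={"n_perm": scheme.n_perm, "seed": scheme.seed, "k": k},
        unit_info={"null": NullDistribution(null, "kth_max")},
    )


def _batch_permutation_p(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """permutation_p for many observed values against one null (vectorized:
    p_v = #{null >= obs_v}/n_perm via a sorted-null search)."""
    srt = np.sort(null)
    # count of null values >= obs  ==  n - searchsorted(null, obs, 'left')
    cnt = null.size - np.searchsorted(srt, observed, side="left")
    return cnt / null.size


def _max_cluster_extent(sup: np.ndarray, structure: np.ndarray) -> int:
    lab, n = ndimage.label(sup, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_extent_correct(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    mask: np.ndarray | None,
    scheme: PermutationScheme,
    primary_p: float = 0.001,
    connectivity: int = 26,
    alpha: float = 0.05,
) -> CorrectionResult:
    """Cluster-extent permutation correction.

    Clusters are formed where |r| exceeds the correlation threshold
    corresponding to the two-sided primary p; the null records the maximal
    cluster extent per permutation.
    """
    if not 0 < primary_p < 1:
        raise ValueError("primary_p must lie in (0, 1)")
    eng = CorrelationPermutationEngine(stack, covariate, mask)
    r_thr = p_to_statistic_threshold(primary_p, eng.n_subjects, two_sided=True)
    structure = binary_structure(connectivity)

    null = np.empty(scheme.n_perm)
    for i, perm in enumerate(scheme.permutations):
        vol = np.abs(eng.rvolume(perm))
        null[i] = _max_cluster_extent((vol >= r_thr) & eng.mask, structure)

    obs_vol = np.abs(eng.rvolume())
    sup = (obs_vol >= r_thr) & eng.mask
    lab, n_clusters = ndimage.label(sup, structure=structure)
    if n_clusters == 0:
        return CorrectionResult(
            level="cluster", adjusted_p=np.empty(0), sig_mask=np.zeros_like(sup),
            alpha=alpha, method="perm-cluster", mask=eng.mask,
            params={"n_perm": scheme.n_perm, "primary_p": primary_p,
                    "r_threshold": r_thr, "connectivity": connectivity, "n_clusters": 0},
        )
    extents = np.bincount(lab.ravel())[1:]
    adj = _batch_permutation_p(extents.astype(float), null)
    sig_clusters = np.nonzero(adj <= alpha)[0] + 1
    sig = np.isin(lab, sig_clusters)
    return CorrectionResult(
        level="cluster", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="perm-cluster", mask=eng.mask,
        params={"n_perm": scheme.n_perm, "primary_p": primary_p, "r_threshold": r_thr,
                "connectivity": connectivity, "n_clusters": int(n_clusters),
                "extents": extents.tolist()},
        unit_info={"unit_labels": lab, "null": NullDistribution(null, "max_cluster_extent")},
    )


def _tfce_thresholds(vmax: float, params: TFCEParams) -> np.ndarray:
    if vmax <= params.t0:
        return np.empty(0)
    k_max = int(math.floor((vmax - params.t0) / params.dt + _TFCE_TOL))
    return params.t0 + params.dt * np.arange(1, k_max + 1)


def _tfce_one_sign(values: np.ndarray, mask: np.ndarray, params: TFCEParams,
                   structure: np.ndarray, out: np.ndarray,
                   extent_scale: float = 1.0) -> None:
    """Accumulate one sign's TFCE scores into ``out``.

    ``extent_scale`` multiplies cluster extents before the E exponent; the
    anatomy-scaled variant passes e_max/e_X here (1.0 leaves extents as-is).
    """
    vmax = values[mask].max() if mask.any() else 0.0
    for t in _tfce_thresholds(vmax, params):
        sup = (values >= t * (1.0 - _TFCE_TOL)) & mask
        if not sup.any():
            break
        lab, _ = ndimage.label(sup, structure=structure)
        counts = np.bincount(lab.ravel()) * extent_scale
        out[sup] += counts[lab[sup]] ** params.E * t**params.H * params.dt


def tfce_transform(
    statmap: StatMap | np.ndarray,
    params: TFCEParams | None = None,
    connectivity: int = 26,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement score per voxel.

    Riemann sum over thresholds ``t = t0+dt, t0+2dt, ... <= max`` of
    ``e(t)^E · t^H · dt`` where e(t) is the extent of the connected
    supra-threshold cluster containing the voxel. Negative signal is handled
    by a second pass over the negated map; the two passes have disjoint
    support and are merged by maximum.
    """
    params = params or TFCEParams()
    if isinstance(statmap, StatMap):
        values, vmask = statmap.values, statmap.mask
    else:
        values = np.asarray(statmap, dtype=float)
        vmask = np.ones(values.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    structure = binary_structure(connectivity)
    pos = np.zeros(values.shape, dtype=float)
    neg = np.zeros(values.shape, dtype=float)
    _tfce_one_sign(values, vmask, params, structure, pos)
    _tfce_one_sign(-values, vmask, params, structure, neg)
    return np.maximum(pos, neg)


def tfce_fwer_correct(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    mask: np.ndarray | None,
    scheme: PermutationScheme,
    params: TFCEParams | None = None,
    connectivity: int = 26,
    alpha: float = 0.05,
) -> CorrectionResult:
    """TFCE permutation correction: per-voxel p against the max-TFCE null."""
    params = params or TFCEParams()
    eng = CorrelationPermutationEngine(stack, covariate, mask)

    null = np.empty(scheme.n_perm)
    obs_scores = None
    for i, perm in enumerate(scheme.permutations):
        vol = eng.rvolume(perm)
        scores = tfce_transform(vol, params, connectivity, mask=eng.mask)
        null[i] = scores[eng.mask].max() if eng.mask.any() else 0.0
        if i == 0:
            obs_scores = scores

    obs = obs_scores[eng.mask]
    adj = _batch_permutation_p(obs, null)
    sig = np.zeros(eng.mask.shape, dtype=bool)
    sig[eng.mask] = adj <= alpha
    return CorrectionResult(
        level="voxel", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="tfce", mask=eng.mask,
        params={"n_perm": scheme.n_perm, "H": params.H, "E": params.E,
                "dt": params.dt, "t0": params.t0, "connectivity": connectivity},
        unit_info={"null": NullDistribution(null, "max_tfce"), "tfce_scores": obs_scores},
    )
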