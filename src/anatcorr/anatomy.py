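"""Anatomy-aware FWER corrections.

Four ways of injecting a reference segmentation into the correction step:

* **Per-organ weighted statistic** — each structure C_k gets the signal
  ``S_k = (1/|U_k|) · sum_{i in U_k} x_i · a_k(i)`` over its support U_k with
  voxelwise accuracy weights a_k; per-organ permutation p-values (each organ
  against its own null, avoiding cross-organ normalization) are Holm-adjusted
  across the K structures.
* **Anatomy-scaled TFCE** — cluster support grows only inside each structure
  and the extent is rescaled by e_max/e_X, so a small activation filling a
  small organ scores like a proportionally larger one in the largest organ.
* **Organ-constrained scaled cluster extent** — the cluster-extent permutation
  test with clusters confined to structures and extents scaled by e_max/e_X.
* **Anatomy-restricted CBA** — correlation-based prepartition clustering whose
  merges never cross structure boundaries.

Background (label 0) voxels are excluded from the anatomy-aware corrections by
default; ``strict=True`` raises instead, for pipelines that require every
analysis voxel to carry a label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._util import binary_structure, center_normalize_rows, neighbor_offsets
from .datatypes import CorrectionResult, CovariateVector, Segmentation, StatMap
from .parametric import holm_adjust
from .permutation import (
    CorrelationPermutationEngine,
    NullDistribution,
    PermutationScheme,
    TFCEParams,
    _batch_permutation_p,
    _tfce_one_sign,
)
from .statmap import p_to_statistic_threshold, statistic_to_p

__all__ = [
    "AccuracyMap",
    "OrganResult",
    "ClusterSet",
    "accuracy_from_annotations",
    "accuracy_from_border",
    "organ_weighted_signal",
    "organ_level_test",
    "scaled_extent",
    "anatomical_tfce",
    "anatomical_cluster_extent_correct",
    "cba_clusters",
    "cba_correct",
    "kmax_bound_from_segmentation",
]

logger = logging.getLogger(__name__)


@dataclass
class AccuracyMap:
    """Per-structure voxel weights a_k(i) in [0, 1] on supports U_k.

    ``supports`` maps each label to the flat voxel indices of U_k and
    ``weights`` to the matching weight vector. Provenance records whether the
    weights came from annotator agreement (n_i/N) or border down-weighting.
    """

    shape: tuple[int, int, int]
    supports: dict[int, np.ndarray]
    weights: dict[int, np.ndarray]
    provenance: str

    def __post_init__(self) -> None:
        for k, idx in self.supports.items():
            w = self.weights[k]
            if idx.size == 0:
                raise ValueError(f"empty support for structure {k}")
            if idx.size != w.size:
                raise ValueError(f"support/weight size mismatch for structure {k}")
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"weights outside [0, 1] for structure {k}")

    @property
    def structure_labels(self) -> list[int]:
        return sorted(self.supports)

    def weight_volume(self, label: int) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=float)
        vol.ravel()[self.supports[label]] = self.weights[label]
        return vol


def accuracy_from_annotations(annotations: list[Segmentation], label: int) -> AccuracyMap:
    """Accuracy weights from annotator agreement: a_k(i) = n_i / N.

    U_k is every voxel that at least one of the N annotators assigned to the
    structure; its weight is the fraction of annotators agreeing.
    """
    if not annotations:
        raise ValueError("at least one annotation is required")
    shape = annotations[0].labels.shape
    for ann in annotations[1:]:
        if ann.labels.shape != shape:
            raise ValueError("annotation grids disagree")
    N = len(annotations)
    votes = np.zeros(shape, dtype=np.int64)
    for ann in annotations:
        votes += ann.labels == label
    idx = np.flatnonzero(votes.ravel())
    if idx.size == 0:
        raise ValueError(f"no annotator labelled any voxel as {label}")
    w = votes.ravel()[idx] / N
    return AccuracyMap(shape, {label: idx}, {label: w}, provenance=f"annotations(N={N})")


def accuracy_from_border(
    segmentation: Segmentation,
    inner_w: float = 1.0,
    border_w: float = 0.1,
    connectivity: int = 26,
) -> AccuracyMap:
    """Border-down-weighted accuracy: the 1-voxel-thick outermost layer of each
    structure gets ``border_w``, the interior ``inner_w``.

    A structure with no interior (thin or single-voxel) is entirely border.
    """
    if not 0 <= border_w <= inner_w <= 1:
        raise ValueError("need 0 <= border_w <= inner_w <= 1")
    structure = binary_structure(connectivity)
    supports: dict[int, np.ndarray] = {}
    weights: dict[int, np.ndarray] = {}
    for lab in segmentation.organ_labels:
        supp = segmentation.labels == lab
        interior = ndimage.binary_erosion(supp, structure=structure)
        w = np.where(interior, inner_w, border_w)
        idx = np.flatnonzero(supp.ravel())
        supports[lab] = idx
        weights[lab] = w.ravel()[idx]
    return AccuracyMap(
        segmentation.labels.shape, supports, weights,
        provenance=f"border_approx(inner={inner_w}, border={border_w})",
    )


def uniform_accuracy(segmentation: Segmentation) -> AccuracyMap:
    """Unit weights on every structure support (plain per-organ means)."""
    supports = {
        lab: np.flatnonzero((segmentation.labels == lab).ravel())
        for lab in segmentation.organ_labels
    }
    weights = {lab: np.ones(idx.size) for lab, idx in supports.items()}
    return AccuracyMap(segmentation.labels.shape, supports, weights, provenance="uniform")


def organ_weighted_signal(statmap: StatMap | np.ndarray, accuracy: AccuracyMap, label: int) -> float:
    """Weighted organ signal ``S_k = (1/|U_k|) · sum_i x_i · a_k(i)``.

    Note the division by the support size |U_k|, not by the weight sum: down-
    weighted border voxels dilute rather than renormalize the average.
    """
    values = statmap.values if isinstance(statmap, StatMap) else np.asarray(statmap, float)
    if label not in accuracy.supports:
        raise KeyError(f"structure {label} not in accuracy map")
    idx = accuracy.supports[label]
    if isinstance(statmap, StatMap):
        inside = statmap.mask.ravel()[idx]
        if not inside.all():
            raise ValueError(f"support of structure {label} extends outside the map mask")
    x = values.ravel()[idx]
    return float(x @ accuracy.weights[label] / idx.size)


@dataclass
class OrganResult:
    """Per-structure weighted-signal test outcome."""

    table: pd.DataFrame  # columns: label, name, S, p, p_holm, significant
    alpha: float
    sig_mask: np.ndarray
    n_perm: int

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].any())

    @property
    def n_significant_voxels(self) -> int:
        return int(self.sig_mask.sum())

    @property
    def level(self) -> str:
        return "organ"


def organ_level_test(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    segmentation: Segmentation,
    scheme: PermutationScheme,
    accuracy: AccuracyMap | None = None,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> OrganResult:
    """Permutation test of the accuracy-weighted organ signal, Holm-adjusted.

    Per permutation the voxelwise r map is recomputed and each organ's |S_k|
    compared against that organ's own permutation distribution (cross-organ
    max statistics would require normalizing signals across organs of very
    different size and label confidence, so each organ keeps its own null).
    """
    if accuracy is None:
        accuracy = uniform_accuracy(segmentation)
    if mask is None:
        mask = segmentation.body_mask
    eng = CorrelationPermutationEngine(stack, covariate, mask)

    # map each support into positions within the engine's masked voxel vector
    flat_pos = np.full(int(np.prod(eng.shape)), -1, dtype=np.intp)
    flat_pos[np.flatnonzero(eng.mask.ravel())] = np.arange(eng.n_voxels)
    organ_pos: dict[int, np.ndarray] = {}
    organ_w: dict[int, np.ndarray] = {}
    labels = sorted(set(accuracy.structure_labels) & set(segmentation.organ_labels))
    if not labels:
        raise ValueError("no structures shared between accuracy map and segmentation")
    skipped = []
    for lab in labels:
        pos = flat_pos[accuracy.supports[lab]]
        keep = pos >= 0
        if not keep.any():
            # e.g. every support voxel had a constant series and was dropped
            skipped.append(lab)
            continue
        if not keep.all():
            logger.warning(
                "structure %d: %d support voxels outside the analysis mask are ignored",
                lab, int((~keep).sum()),
            )
        organ_pos[lab] = pos[keep]
        organ_w[lab] = accuracy.weights[lab][keep]
    if skipped:
        logger.warning("structures with no testable voxels were skipped: %s", skipped)
        labels = [lab for lab in labels if lab not in skipped]
    if not labels:
        raise ValueError("no structure has testable voxels in the analysis mask")

    K = len(labels)
    S = np.empty((scheme.n_perm, K))
    for i, perm in enumerate(scheme.permutations):
        r = eng.rvec(perm)
        for j, lab in enumerate(labels):
            S[i, j] = r[organ_pos[lab]] @ organ_w[lab] / organ_pos[lab].size

    absS = np.abs(S)
    p_raw = (absS >= absS[0][None, :]).mean(axis=0)
    p_holm = holm_adjust(p_raw)
    significant = p_holm <= alpha

    sig_mask = np.zeros(eng.mask.shape, dtype=bool)
    for j, lab in enumerate(labels):
        if significant[j]:
            sig_mask |= segmentation.labels == lab
    sig_mask &= eng.mask

    table = pd.DataFrame(
        {
            "label": labels,
            "name": [segmentation.label_table[lab] for lab in labels],
            "S": S[0],
            "p": p_raw,
            "p_holm": p_holm,
            "significant": significant,
        }
    )
    return OrganResult(table=table, alpha=alpha, sig_mask=sig_mask, n_perm=scheme.n_perm)


def scaled_extent(extent: float, e_X: int, e_max: int) -> float:
    """Organ-scaled cluster extent ``e · e_max / e_X``: the equivalent extent
    in the largest structure, making extents comparable across organ sizes."""
    if e_X < 1 or e_max < e_X:
        raise ValueError("need 1 <= e_X <= e_max")
    return extent * e_max / e_X


def _check_labels(mask: np.ndarray, segmentation: Segmentation, strict: bool) -> np.ndarray:
    unlabelled = mask & ~segmentation.body_mask
    if unlabelled.any():
        if strict:
            raise ValueError(
                f"{int(unlabelled.sum())} masked voxels carry no structure label"
            )
        mask = mask & segmentation.body_mask
    return mask


def anatomical_tfce(
    statmap: StatMap | np.ndarray,
    segmentation: Segmentation,
    params: TFCEParams | None = None,
    connectivity: int = 26,
    mask: np.ndarray | None = None,
    strict: bool = False,
) -> np.ndarray:
    """Anatomy-scaled TFCE: per-voxel ``sum_t (e(t)·e_max/e_X)^E · t^H · dt``.

    Identical to :func:`anatcorr.permutation.tfce_transform` except that
    connected components are computed within each structure's support and the
    extent is scaled by e_max/e_X before exponentiation. With a single
    structure covering the whole mask the two transforms coincide.
    """
    params = params or TFCEParams()
    if isinstance(statmap, StatMap):
        values, vmask = statmap.values, statmap.mask
    else:
        values = np.asarray(statmap, dtype=float)
        vmask = np.ones(values.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    vmask = _check_labels(vmask, segmentation, strict)
    structure = binary_structure(connectivity)
    e_max = segmentation.e_max

    out = np.zeros(values.shape, dtype=float)
    for lab, e_X in segmentation.organ_extents.items():
        organ_mask = (segmentation.labels == lab) & vmask
        if not organ_mask.any():
            continue
        # crop to the structure's bounding box; components cannot leave it
        sl = ndimage.find_objects(organ_mask.astype(np.int8))[0]
        sub_vals = values[sl]
        sub_mask = organ_mask[sl]
        sub_out = np.zeros(sub_vals.shape, dtype=float)
        scale = e_max / e_X
        _tfce_one_sign(sub_vals, sub_mask, params, structure, sub_out, scale)
        neg_out = np.zeros(sub_vals.shape, dtype=float)
        _tfce_one_sign(-sub_vals, sub_mask, params, structure, neg_out, scale)
        out[sl] += np.maximum(sub_out, neg_out)
    return out


def anatomical_tfce_fwer_correct(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    segmentation: Segmentation,
    scheme: PermutationScheme,
    params: TFCEParams | None = None,
    connectivity: int = 26,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    strict: bool = False,
) -> CorrectionResult:
    """Permutation FWER correction with the anatomy-scaled TFCE statistic."""
    params = params or TFCEParams()
    if mask is None:
        mask = segmentation.body_mask
    mask = _check_labels(np.asarray(mask, bool), segmentation, strict)
    eng = CorrelationPermutationEngine(stack, covariate, mask)

    null = np.empty(scheme.n_perm)
    obs_scores = None
    for i, perm in enumerate(scheme.permutations):
        vol = eng.rvolume(perm)
        scores = anatomical_tfce(vol, segmentation, params, connectivity, mask=eng.mask)
        null[i] = scores[eng.mask].max() if eng.mask.any() else 0.0
        if i == 0:
            obs_scores = scores

    obs = obs_scores[eng.mask]
    adj = _batch_permutation_p(obs, null)
    sig = np.zeros(eng.mask.shape, dtype=bool)
    sig[eng.mask] = adj <= alpha
    return CorrectionResult(
        level="voxel", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="anat-tfce", mask=eng.mask,
        params={"n_perm": scheme.n_perm, "H": params.H, "E": params.E,
                "dt": params.dt, "t0": params.t0, "connectivity": connectivity},
        unit_info={"null": NullDistribution(null, "max_tfce"), "tfce_scores": obs_scores},
    )


def _organ_clusters(vol_abs: np.ndarray, mask: np.ndarray, segmentation: Segmentation,
                    r_thr: float, structure: np.ndarray, join: bool):
    """Per-organ supra-threshold clusters with scaled extents.

    Yields (label, member_mask, scaled_extent) per cluster (or per organ when
    ``join`` merges all of an organ's clusters into one unit).
    """
    e_max = segmentation.e_max
    for lab, e_X in segmentation.organ_extents.items():
        organ_sup = (vol_abs >= r_thr) & mask & (segmentation.labels == lab)
        if not organ_sup.any():
            continue
        if join:
            yield lab, organ_sup, scaled_extent(int(organ_sup.sum()), e_X, e_max)
            continue
        cl, n = ndimage.label(organ_sup, structure=structure)
        counts = np.bincount(cl.ravel())
        for ci in range(1, n + 1):
            yield lab, cl == ci, scaled_extent(int(counts[ci]), e_X, e_max)


def anatomical_cluster_extent_correct(
    stack: np.ndarray,
    covariate: CovariateVector | np.ndarray,
    segmentation: Segmentation,
    scheme: PermutationScheme,
    primary_p: float = 0.001,
    connectivity: int = 26,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    join_within_organ: bool = False,
    strict: bool = False,
) -> CorrectionResult:
    """Organ-constrained cluster-extent permutation correction.

    Clusters grow only inside individual structures; each cluster's statistic
    is its extent scaled by e_max/e_X, and the null records the maximal scaled
    extent per permutation. Multiple clusters within one organ are tested
    separately by default (``join_within_organ=True`` pools them).
    """
    if not 0 < primary_p < 1:
        raise ValueError("primary_p must lie in (0, 1)")
    if mask is None:
        mask = segmentation.body_mask
    mask = _check_labels(np.asarray(mask, bool), segmentation, strict)
    eng = CorrelationPermutationEngine(stack, covariate, mask)
    r_thr = p_to_statistic_threshold(primary_p, eng.n_subjects, two_sided=True)
    structure = binary_structure(connectivity)

    null = np.empty(scheme.n_perm)
    for i, perm in enumerate(scheme.permutations):
        vol = np.abs(eng.rvolume(perm))
        stat = 0.0
        for _, _, s in _organ_clusters(vol, eng.mask, segmentation, r_thr,
                                       structure, join_within_organ):
            stat = max(stat, s)
        null[i] = stat

    obs_vol = np.abs(eng.rvolume())
    organ_of, extents, unit_labels = [], [], np.zeros(eng.mask.shape, dtype=np.int32)
    for lab, members, s in _organ_clusters(obs_vol, eng.mask, segmentation, r_thr,
                                           structure, join_within_organ):
        organ_of.append(lab)
        extents.append(s)
        unit_labels[members] = len(extents)

    if not extents:
        return CorrectionResult(
            level="cluster", adjusted_p=np.empty(0), sig_mask=np.zeros(eng.mask.shape, bool),
            alpha=alpha, method="anat-cluster", mask=eng.mask,
            params={"n_perm": scheme.n_perm, "primary_p": primary_p, "r_threshold": r_thr,
                    "connectivity": connectivity, "n_clusters": 0,
                    "join_within_organ": join_within_organ},
        )
    extents = np.asarray(extents, dtype=float)
    adj = _batch_permutation_p(extents, null)
    sig_ids = np.nonzero(adj <= alpha)[0] + 1
    sig = np.isin(unit_labels, sig_ids) & (unit_labels > 0)
    return CorrectionResult(
        level="cluster", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method="anat-cluster", mask=eng.mask,
        params={"n_perm": scheme.n_perm, "primary_p": primary_p, "r_threshold": r_thr,
                "connectivity": connectivity, "n_clusters": len(extents),
                "scaled_extents": extents.tolist(), "organ_labels": organ_of,
                "join_within_organ": join_within_organ},
        unit_info={"unit_labels": unit_labels,
                   "null": NullDistribution(null, "max_scaled_extent")},
    )


@dataclass
class ClusterSet:
    """A full partition of the analysis mask into prepartition clusters."""

    cluster_labels: np.ndarray  # 3D int volume; 0 outside, 1..n_clusters inside
    connectivity: int
    primary_threshold: float | None = None

    def __post_init__(self) -> None:
        self.cluster_labels = np.asarray(self.cluster_labels)
        if self.cluster_labels.ndim != 3:
            raise ValueError("cluster_labels must be a 3D volume")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max())

    @property
    def mask(self) -> np.ndarray:
        return self.cluster_labels > 0

    @property
    def extents(self) -> np.ndarray:
        return np.bincount(self.cluster_labels.ravel(), minlength=self.n_clusters + 1)[1:]

    def members(self, i: int) -> np.ndarray:
        """Flat voxel indices of cluster i (1-based)."""
        return np.flatnonzero(self.cluster_labels.ravel() == i)

    def is_partition_of(self, mask: np.ndarray) -> bool:
        return bool(np.array_equal(self.mask, np.asarray(mask, bool)))


def cba_clusters(
    pilot_stack: np.ndarray,
    mask: np.ndarray | None = None,
    connectivity: int = 26,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    segmentation: Segmentation | None = None,
) -> ClusterSet:
    """Correlation-based prepartition clustering (the CBA clustering step).

    Each voxel links to the neighbour with the highest pilot-series
    correlation divided by the physical distance between voxel centres (so
    edge/vertex neighbours on an anisotropic grid are handicapped by their
    larger separation). Clusters are the connected components of the
    undirected union of those best-neighbour links — a deterministic rule:
    score ties are broken toward the lowest linear voxel index.

    The pilot stack must be data not reused in the subsequent analysis (a
    reference image set), with at least 3 samples per voxel. Voxels with a
    constant pilot series cannot be correlated and become singleton clusters.
    With a segmentation, links never cross structure boundaries and the mask
    defaults to the labelled body.
    """
    pilot_stack = np.asarray(pilot_stack, dtype=float)
    if pilot_stack.ndim != 4 or pilot_stack.shape[-1] < 3:
        raise ValueError("pilot stack must be 4D with >= 3 samples")
    shape = pilot_stack.shape[:3]
    if mask is None:
        mask = segmentation.body_mask if segmentation is not None else np.ones(shape, bool)
    mask = np.asarray(mask, dtype=bool)
    if segmentation is not None and segmentation.labels.shape != shape:
        raise ValueError("segmentation grid does not match the pilot stack")

    # voxelwise normalized pilot series; constant series flagged invalid
    flat = pilot_stack.reshape(-1, pilot_stack.shape[-1])
    Pn, valid_rows = center_normalize_rows(flat)
    P = Pn.reshape(pilot_stack.shape)
    valid = valid_rows.reshape(shape) & mask
    n_const = int((mask & ~valid).sum())
    if n_const:
        logger.warning("%d voxels with constant pilot series become singleton clusters", n_const)

    sy, sz = shape[1], shape[2]
    offsets = sorted(neighbor_offsets(connectivity),
                     key=lambda d: d[0] * sy * sz + d[1] * sz + d[2])

    best_score = np.full(shape, -np.inf)
    best_nb = np.full(shape, -1, dtype=np.int64)
    flat_index = np.arange(int(np.prod(shape))).reshape(shape)
    for d in offsets:
        src, dst = [], []
        for ax, dd in enumerate(d):
            n_ax = shape[ax]
            if dd >= 0:
                src.append(slice(0, n_ax - dd))
                dst.append(slice(dd, n_ax))
            else:
                src.append(slice(-dd, n_ax))
                dst.append(slice(0, n_ax + dd))
        src, dst = tuple(src), tuple(dst)
        ok = valid[src] & valid[dst]
        if segmentation is not None:
            ok &= segmentation.labels[src] == segmentation.labels[dst]
        if not ok.any():
            continue
        corr = np.einsum("...s,...s->...", P[src], P[dst])
        dist = math.sqrt(sum((dd * v) ** 2 for dd, v in zip(d, voxel_size)))
        score = np.where(ok, corr / dist, -np.inf)
        improve = score > best_score[src]
        bs = best_score[src]
        bn = best_nb[src]
        bs[improve] = score[improve]
        bn[improve] = flat_index[dst][improve]
        best_score[src] = bs
        best_nb[src] = bn

    node_id = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    mask_idx = np.flatnonzero(mask.ravel())
    node_id[mask_idx] = np.arange(mask_idx.size)
    has_link = best_nb.ravel()[mask_idx] >= 0
    rows = node_id[mask_idx[has_link]]
    cols = node_id[best_nb.ravel()[mask_idx[has_link]]]
    if np.any(cols < 0):
        raise RuntimeError("best-neighbour link points outside the mask")
    n_nodes = mask_idx.size
    graph = coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    _, comp = connected_components(graph, directed=False)

    cluster_labels = np.zeros(shape, dtype=np.int32)
    cluster_labels.ravel()[mask_idx] = comp + 1
    return ClusterSet(cluster_labels, connectivity=connectivity)


def cba_correct(
    statmap: StatMap,
    clusters: ClusterSet,
    inner_method: str = "holm",
    stack: np.ndarray | None = None,
    covariate: CovariateVector | np.ndarray | None = None,
    scheme: PermutationScheme | None = None,
    alpha: float = 0.05,
) -> CorrectionResult:
    """Correction on prepartition clusters treated as units.

    Each cluster's signal is the mean of its member voxels' statistic values.
    ``inner_method="holm"`` converts the mean r to a p-value through the same
    t transform as single voxels (an approximation: the mean of correlations
    is not itself a correlation coefficient) and Holm-adjusts across clusters;
    ``inner_method="perm-voxel"`` runs the max-statistic permutation test on
    the recomputed cluster means. Significance is broadcast to member voxels.
    """
    if statmap.scale != "r":
        raise ValueError("cba_correct expects an r-scale map")
    if not clusters.is_partition_of(statmap.mask):
        raise ValueError("clusters do not partition the analysis mask")
    lab = clusters.cluster_labels
    counts = np.bincount(lab[statmap.mask], minlength=clusters.n_clusters + 1)[1:]
    sums = np.bincount(lab[statmap.mask], weights=statmap.values[statmap.mask],
                       minlength=clusters.n_clusters + 1)[1:]
    signals = sums / counts

    if inner_method == "holm":
        mean_map = StatMap(
            values=np.clip(signals, -1, 1).reshape(-1, 1, 1),
            scale="r",
            mask=np.ones((signals.size, 1, 1), bool),
            n=statmap.n,
        )
        p_c = statistic_to_p(mean_map, two_sided=True).values.ravel()
        adj = holm_adjust(p_c)
        null = None
    elif inner_method == "perm-voxel":
        if stack is None or covariate is None or scheme is None:
            raise ValueError("perm-voxel inner correction needs stack, covariate, and scheme")
        eng = CorrelationPermutationEngine(stack, covariate, statmap.mask)
        if not np.array_equal(eng.mask, statmap.mask):
            raise ValueError("stack produces a different analysis mask than the stat map")
        lab_m = lab[statmap.mask]
        nullv = np.empty(scheme.n_perm)
        for i, perm in enumerate(scheme.permutations):
            r = eng.rvec(perm)
            means = np.bincount(lab_m, weights=r, minlength=clusters.n_clusters + 1)[1:] / counts
            nullv[i] = np.abs(means).max()
        adj = _batch_permutation_p(np.abs(signals), nullv)
        null = NullDistribution(nullv, "max_abs_voxel")
    else:
        raise ValueError("inner_method must be 'holm' or 'perm-voxel'")

    sig_ids = np.nonzero(adj <= alpha)[0] + 1
    sig = np.isin(lab, sig_ids) & statmap.mask
    info: dict = {"unit_labels": lab, "signals": signals}
    if null is not None:
        info["null"] = null
    return CorrectionResult(
        level="cluster", adjusted_p=adj, sig_mask=sig, alpha=alpha,
        method=f"cba[{inner_method}]", mask=statmap.mask,
        params={"n_clusters": clusters.n_clusters, "inner_method": inner_method},
        unit_info=info,
    )


def kmax_bound_from_segmentation(segmentation: Segmentation, fraction: float = 1.0) -> int:
    """Anatomy-informed upper bound for k in k-FWER control: (a fraction of)
    the smallest structure extent, so allowed errors can never swamp the
    smallest organ's inference."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, int(math.floor(fraction * min(segmentation.organ_extents.values()))))
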