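"""Evaluation protocols: nominal-FWER calibration on null data, and
activity-retention counting against a known-truth mask.

The null protocol mirrors the random-correlate design: one fixed (signal-
bearing or signal-free) image stack, and per run a fresh standard-normal
covariate that no voxel truly co-varies with. The nominal FWER of a method is
the fraction of runs in which anything at all survives its correction. Note
the caveat inherited from the design: a random correlate makes the global null
true by construction here (synthetic noise), but on real data it does not
guarantee the null at every voxel, so the reported rate is an approximation of
the certified error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import binary_structure, substream
from .anatomy import (
    ClusterSet,
    accuracy_from_border,
    anatomical_cluster_extent_correct,
    anatomical_tfce_fwer_correct,
    cba_clusters,
    cba_correct,
    kmax_bound_from_segmentation,
    organ_level_test,
)
from .datatypes import CorrectionResult, CovariateVector, Segmentation
from .parametric import (
    bonferroni_adjust,
    estimate_smoothness,
    holm_adjust,
    rft_cluster_correct,
    rft_voxel_correct,
)
from .permutation import (
    TFCEParams,
    cluster_extent_correct,
    generate_permutations,
    kmax_fwer_correct,
    tfce_fwer_correct,
    voxel_fwer_correct,
)
from .phantom import PhantomConfig, make_null_covariate, make_segmentation, simulate_subjects
from .statmap import fisher_z, statistic_to_p, voxelwise_correlation

__all__ = [
    "CalibrationReport",
    "RetentionReport",
    "run_null_calibration",
    "activity_retention",
    "standard_method_suite",
    "STANDARD_METHODS",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationReport:
    """Nominal FWER per method over repeated null analyses."""

    n_runs: int
    alpha: float
    runs_with_any_significance: dict[str, int]
    active_voxel_counts: dict[str, list[int]]
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def nominal_fwer(self) -> dict[str, float]:
        return {
            m: k / self.n_runs for m, k in self.runs_with_any_significance.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, k in self.runs_with_any_significance.items():
            counts = self.active_voxel_counts[m]
            rows.append(
                {
                    "method": m,
                    "n_runs": self.n_runs,
                    "runs_with_any_significance": k,
                    "nominal_fwer": k / self.n_runs,
                    "mean_active_voxels": float(np.mean(counts)) if counts else 0.0,
                    "max_active_voxels": int(np.max(counts)) if counts else 0,
                    "note": self.notes.get(m, ""),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RetentionReport:
    """Significant-voxel counts inside/outside a truth mask."""

    retained_true: int
    detected_outside: int
    truth_size: int

    @property
    def retention_fraction(self) -> float:
        return self.retained_true / self.truth_size if self.truth_size else 0.0


def run_null_calibration(
    config: PhantomConfig,
    methods: dict,
    n_runs: int,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> CalibrationReport:
    """Estimate nominal FWERs over repeated null-covariate analyses.

    A phantom segmentation and subject stack are generated once from
    ``config``; each run draws a fresh standard-normal covariate and applies
    every method. ``methods`` maps a name to a callable
    ``f(stack, covariate, mask, segmentation, seed) -> result`` where the
    result exposes ``any_significant`` and ``n_significant_voxels`` (see
    :func:`standard_method_suite`). A method that raises is dropped from the
    remaining runs with a logged note; the others continue.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seg = make_segmentation(config)
    gen_cov = make_null_covariate(config.n_subjects, config.seed)
    stack = simulate_subjects(seg, gen_cov, config)
    mask = seg.body_mask

    seed_rng = substream(master_seed, "calibration-runs")
    run_seeds = seed_rng.integers(0, 2**31 - 1, size=n_runs)

    hits = {m: 0 for m in methods}
    counts: dict[str, list[int]] = {m: [] for m in methods}
    notes: dict[str, str] = {}
    failed: set[str] = set()
    for i in range(n_runs):
        covariate = make_null_covariate(config.n_subjects, int(run_seeds[i]))
        for name, fn in methods.items():
            if name in failed:
                continue
            try:
                res = fn(stack, covariate, mask, seg, int(run_seeds[i]))
            except Exception as exc:  # noqa: BLE001 — isolate per-method failures
                logger.exception("method %s failed on run %d; dropping it", name, i)
                notes[name] = f"failed on run {i}: {exc}"
                failed.add(name)
                continue
            if res.any_significant:
                hits[name] += 1
            counts[name].append(res.n_significant_voxels)

    for name in failed:
        hits.pop(name, None)
    return CalibrationReport(
        n_runs=n_runs, alpha=alpha, runs_with_any_significance=hits,
        active_voxel_counts=counts, notes=notes,
    )


def activity_retention(
    result: CorrectionResult,
    truth_mask: np.ndarray,
    erode_boundary: bool = False,
    connectivity: int = 6,
) -> RetentionReport:
    """Count significant voxels inside and outside a truth mask.

    With ``erode_boundary`` the outermost truth layer is excluded from both
    counts, accommodating registration/segmentation uncertainty at organ
    borders.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    sig = result.sig_mask
    if sig.shape != truth_mask.shape:
        raise ValueError("truth mask grid does not match the result")
    core = (
        ndimage.binary_erosion(truth_mask, structure=binary_structure(connectivity))
        if erode_boundary
        else truth_mask
    )
    retained = int((sig & core).sum())
    outside = int((sig & ~truth_mask).sum())
    return RetentionReport(retained_true=retained, detected_outside=outside,
                           truth_size=int(core.sum()))


# ---------------------------------------------------------------------------
# standard method suite


def _uncorrected(alpha):
    def fn(stack, covariate, mask, seg, seed):
        rmap = voxelwise_correlation(stack, covariate, mask)
        pmap = statistic_to_p(rmap, two_sided=True)
        p = pmap.values[pmap.mask]
        sig = np.zeros(pmap.mask.shape, bool)
        sig[pmap.mask] = p <= alpha
        return CorrectionResult(level="voxel", adjusted_p=p, sig_mask=sig,
                                alpha=alpha, method="uncorrected", mask=pmap.mask)
    return fn


def _simple_adjust(kind, alpha):
    def fn(stack, covariate, mask, seg, seed):
        rmap = voxelwise_correlation(stack, covariate, mask)
        pmap = statistic_to_p(rmap, two_sided=True)
        p = pmap.values[pmap.mask]
        adj = bonferroni_adjust(p) if kind == "bonferroni" else holm_adjust(p)
        sig = np.zeros(pmap.mask.shape, bool)
        sig[pmap.mask] = adj <= alpha
        return CorrectionResult(level="voxel", adjusted_p=adj, sig_mask=sig,
                                alpha=alpha, method=kind, mask=pmap.mask)
    return fn


def _residuals(stack, covariate):
    """Residual stack after removing the voxelwise linear covariate fit."""
    c = covariate.values if isinstance(covariate, CovariateVector) else np.asarray(covariate, float)
    cc = c - c.mean()
    denom = float(cc @ cc)
    Xc = stack - stack.mean(axis=-1, keepdims=True)
    beta = (Xc @ cc) / denom
    return Xc - beta[..., None] * cc


def _rft(kind, alpha, primary_p, connectivity, voxel_size):
    from scipy import stats as _st

    def fn(stack, covariate, mask, seg, seed):
        vs = voxel_size or (seg.voxel_size if seg is not None else (1.0, 1.0, 1.0))
        rmap = voxelwise_correlation(stack, covariate, mask)
        zmap = fisher_z(rmap)
        smooth = estimate_smoothness(_residuals(stack, covariate), zmap.mask, vs)
        if kind == "rft-voxel":
            return rft_voxel_correct(zmap, smooth, alpha)
        primary_z = float(_st.norm.isf(primary_p / 2.0))
        return rft_cluster_correct(zmap, primary_z, smooth, alpha,
                                   connectivity=connectivity, voxel_size=vs)
    return fn


def standard_method_suite(
    names: list[str],
    alpha: float = 0.05,
    n_perm: int = 1000,
    primary_p: float = 0.001,
    connectivity: int = 26,
    tfce_params: TFCEParams | None = None,
    inner_weight: float = 1.0,
    border_weight: float = 0.1,
    k: int | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    pilot_stack: np.ndarray | None = None,
    clusters: ClusterSet | None = None,
    anat_clusters: ClusterSet | None = None,
    join_within_organ: bool = False,
) -> dict:
    """Build ready-to-run correction callables keyed by method name.

    Every callable has the signature
    ``fn(stack, covariate, mask, segmentation, seed) -> result``; permutation
    methods derive their scheme from the passed seed. CBA methods need either
    precomputed ``clusters`` (and ``anat_clusters``) or a ``pilot_stack`` from
    which the partition is computed once and cached.
    """
    tfce_params = tfce_params or TFCEParams()
    out: dict = {}
    cba_cache: dict[str, ClusterSet] = {}
    if clusters is not None:
        cba_cache["cba"] = clusters
    if anat_clusters is not None:
        cba_cache["anat-cba"] = anat_clusters

    def _scheme(stack, seed):
        return generate_permutations(stack.shape[-1], n_perm=n_perm, seed=seed)

    def _get_clusters(name, mask, seg):
        if name not in cba_cache:
            if pilot_stack is None:
                raise ValueError(f"{name} requires precomputed clusters or a pilot stack")
            vs = voxel_size or (seg.voxel_size if seg is not None else (1.0, 1.0, 1.0))
            cba_cache[name] = cba_clusters(
                pilot_stack, mask=mask, connectivity=connectivity, voxel_size=vs,
                segmentation=seg if name == "anat-cba" else None,
            )
        return cba_cache[name]

    for name in names:
        if name == "uncorrected":
            out[name] = _uncorrected(alpha)
        elif name in ("bonferroni", "holm"):
            out[name] = _simple_adjust(name, alpha)
        elif name in ("rft-voxel", "rft-cluster"):
            out[name] = _rft(name, alpha, primary_p, connectivity, voxel_size)
        elif name == "perm-voxel":
            out[name] = lambda stack, cov, mask, seg, seed: voxel_fwer_correct(
                stack, cov, mask, _scheme(stack, seed), alpha)
        elif name == "perm-cluster":
            out[name] = lambda stack, cov, mask, seg, seed: cluster_extent_correct(
                stack, cov, mask, _scheme(stack, seed), primary_p, connectivity, alpha)
        elif name == "perm-kmax":
            def _kmax(stack, cov, mask, seg, seed, _k=k):
                kk = _k if _k is not None else (
                    kmax_bound_from_segmentation(seg) if seg is not None else 1)
                return kmax_fwer_correct(stack, cov, mask, _scheme(stack, seed), kk, alpha)
            out[name] = _kmax
        elif name == "tfce":
            out[name] = lambda stack, cov, mask, seg, seed: tfce_fwer_correct(
                stack, cov, mask, _scheme(stack, seed), tfce_params, connectivity, alpha)
        elif name == "anat-tfce":
            out[name] = lambda stack, cov, mask, seg, seed: anatomical_tfce_fwer_correct(
                stack, cov, seg, _scheme(stack, seed), tfce_params, connectivity,
                alpha, mask=mask)
        elif name == "anat-cluster":
            out[name] = lambda stack, cov, mask, seg, seed: anatomical_cluster_extent_correct(
                stack, cov, seg, _scheme(stack, seed), primary_p, connectivity,
                alpha, mask=mask, join_within_organ=join_within_organ)
        elif name == "organ":
            def _organ(stack, cov, mask, seg, seed):
                acc = accuracy_from_border(seg, inner_weight, border_weight, connectivity)
                return organ_level_test(stack, cov, seg, _scheme(stack, seed),
                                        accuracy=acc, alpha=alpha, mask=mask)
            out[name] = _organ
        elif name in ("cba", "anat-cba"):
            def _cba(stack, cov, mask, seg, seed, _name=name):
                cl = _get_clusters(_name, mask, seg)
                rmap = voxelwise_correlation(stack, cov, cl.mask)
                return cba_correct(rmap, cl, inner_method="perm-voxel", stack=stack,
                                   covariate=cov, scheme=_scheme(stack, seed), alpha=alpha)
            out[name] = _cba
        else:
            raise ValueError(f"unknown method '{name}' (valid: {sorted(STANDARD_METHODS)})")
    return out


STANDARD_METHODS = (
    "uncorrected", "bonferroni", "holm", "rft-voxel", "rft-cluster",
    "perm-voxel", "perm-cluster", "perm-kmax", "tfce",
    "organ", "anat-tfce", "anat-cluster", "cba", "anat-cba",
)
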