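"""Synthetic whole-body phantom: segmentations, subject stacks, covariates.

The phantom emulates the statistical structure the corrections assume, without
any external data: an anisotropic 3D grid with labelled structures of
deliberately varied sizes (including a large "fat shell" playing the role of
subcutaneous fat), spatially smooth subject-to-subject noise, and a covariate
that is linearly correlated with the image signal in designated structures.

Each voxel's value for subject ``s`` is
``effect_by_label[label]·covariate[s] + noise`` with smoothed Gaussian noise
of standard deviation ``noise_sd``, so the population correlation inside a
structure with effect ``a`` is ``a/sqrt(a^2 + noise_sd^2)``: the effect and
the noise level jointly control the expected voxelwise r, and ``noise_sd = 0``
with a nonzero effect gives r = ±1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import substream
from .datatypes import CovariateVector, Segmentation

__all__ = [
    "PhantomConfig",
    "PlacementError",
    "make_segmentation",
    "make_null_covariate",
    "simulate_subjects",
    "active_truth_mask",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


class PlacementError(ValueError):
    """The requested structures do not fit in the volume."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic body phantom.

    voxel_size defaults to a strongly anisotropic grid (2 x 8 x 2 mm),
    mirroring the coarse slice spacing of whole-body MR protocols; smooth_fwhm
    is the Gaussian FWHM (mm) of the subject-to-subject noise field.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 8.0, 2.0)
    n_organs: int = 4
    n_subjects: int = 50
    effect_by_label: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    smooth_fwhm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError("shape must be 3 integers, each >= 8")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.n_organs < 1:
            raise ValueError("n_organs must be >= 1")
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.smooth_fwhm < 0:
            raise ValueError("smooth_fwhm must be nonnegative")
        for lab, eff in self.effect_by_label.items():
            if not -1.0 <= eff <= 1.0:
                raise ValueError(f"effect for label {lab} outside [-1, 1]")


def make_segmentation(config: PhantomConfig) -> Segmentation:
    """Build a deterministic labelled phantom segmentation.

    Label 1 is always the "fat_shell" structure: a solid block when
    ``n_organs == 1``, otherwise the hollow outermost layer of the body box.
    Labels 2..n_organs are interior boxes whose cross-sections shrink from
    organ to organ, guaranteeing at least a 2x extent ratio between the
    smallest and largest structure whenever ``n_organs >= 2``.
    """
    shape = np.array(config.shape)
    labels = np.zeros(config.shape, dtype=np.int32)
    table: dict[int, str] = {}

    # body box leaves a 1-voxel background margin on every face
    lo, hi = np.ones(3, dtype=int), shape - 1

    if config.n_organs == 1:
        labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
        table[1] = "fat_shell"
        return Segmentation(labels, table, config.voxel_size)

    body = np.zeros(config.shape, dtype=bool)
    body[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    interior_full = ndimage.binary_erosion(body, ndimage.generate_binary_structure(3, 1))
    shell = body & ~interior_full
    labels[shell] = 1
    table[1] = "fat_shell"

    # interior region available for organ placement (one voxel in from shell)
    ilo, ihi = lo + 1, hi - 1
    idims = ihi - ilo
    n_inner = config.n_organs - 1
    axis = int(np.argmax(idims))
    seg_len = (idims[axis] - (n_inner - 1)) // n_inner  # 1-voxel gaps
    if seg_len < 2:
        raise PlacementError(
            f"volume {config.shape} too small to place {config.n_organs} organs"
        )
    cross_axes = [a for a in range(3) if a != axis]
    c1, c2 = idims[cross_axes[0]], idims[cross_axes[1]]
    if min(c1, c2) < 2:
        raise PlacementError(
            f"volume {config.shape} too small to place {config.n_organs} organs"
        )

    # plan the interior organ boxes first, then guarantee the size contract
    plan: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(n_inner):
        # shrink cross-section linearly from full size to half size
        frac = 1.0 if n_inner == 1 else 1.0 - 0.5 * j / (n_inner - 1)
        dims = np.empty(3, dtype=int)
        dims[axis] = seg_len
        dims[cross_axes[0]] = max(1, int(np.floor(c1 * frac)))
        dims[cross_axes[1]] = max(1, int(np.floor(c2 * frac)))
        start = np.array(ilo)
        start[axis] = ilo[axis] + j * (seg_len + 1)
        if np.any(start + dims > ihi):
            raise PlacementError("organ placement exceeded the interior region")
        plan.append((start, dims))

    # shrink the smallest organ until the largest structure (shell or organ)
    # is at least twice its extent
    shell_extent = int(shell.sum())
    start, dims = plan[-1]
    while True:
        largest = max(shell_extent, max(int(np.prod(d)) for _, d in plan))
        if largest >= 2 * int(np.prod(dims)):
            break
        shrinkable = [a for a in cross_axes if dims[a] > 1] or (
            [axis] if dims[axis] > 1 else []
        )
        if not shrinkable:
            raise PlacementError("cannot satisfy the 2x size-ratio contract")
        ax = max(shrinkable, key=lambda a: dims[a])
        dims[ax] -= 1

    for j, (start, dims) in enumerate(plan):
        lab = j + 2
        end = start + dims
        block = labels[start[0] : end[0], start[1] : end[1], start[2] : end[2]]
        if np.any(block != 0):
            raise PlacementError("organ placement produced overlapping structures")
        labels[start[0] : end[0], start[1] : end[1], start[2] : end[2]] = lab
        table[lab] = f"organ_{lab}"

    return Segmentation(labels, table, config.voxel_size)


def make_null_covariate(n_subjects: int, seed: int) -> CovariateVector:
    """I.i.d. standard-normal covariate — the null correlate used to probe
    familywise error rates when no voxel truly co-varies with it."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = substream(seed, "null-covariate")
    values = rng.standard_normal(n_subjects)
    ids = [f"S{i:04d}" for i in range(n_subjects)]
    return CovariateVector(ids, values)


def _smooth_noise(
    shape: tuple[int, int, int],
    n_subjects: int,
    noise_sd: float,
    smooth_fwhm: float,
    voxel_size: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    noise = rng.standard_normal((*shape, n_subjects))
    if smooth_fwhm > 0:
        sigma_vox = [smooth_fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
        for s in range(n_subjects):
            noise[..., s] = ndimage.gaussian_filter(noise[..., s], sigma=sigma_vox, mode="nearest")
        # smoothing shrinks the variance; rescale globally so the field's
        # overall standard deviation is noise_sd again
        sd = noise.std()
        if sd > 0:
            noise *= 1.0 / sd
    return noise * noise_sd


def simulate_subjects(
    segmentation: Segmentation,
    covariate: CovariateVector,
    config: PhantomConfig,
) -> np.ndarray:
    """Simulate a 4D subject stack over the phantom segmentation.

    Each voxel's value for subject ``s`` is
    ``effect_by_label[label]·covariate[s] + noise`` (see module docstring).
    """
    if len(covariate) != config.n_subjects:
        raise ValueError("covariate length does not match config.n_subjects")
    if segmentation.labels.shape != config.shape:
        raise ValueError("segmentation grid does not match config.shape")
    present = set(segmentation.organ_labels)
    missing = set(config.effect_by_label) - present
    if missing:
        raise ValueError(f"effect_by_label refers to absent labels: {sorted(missing)}")

    amplitude = np.zeros(config.shape, dtype=float)
    for lab, a in config.effect_by_label.items():
        amplitude[segmentation.labels == lab] = a

    stack = amplitude[..., None] * covariate.values[None, None, None, :]
    if config.noise_sd > 0:
        rng = substream(config.seed, "subject-noise")
        stack = stack + _smooth_noise(
            config.shape, config.n_subjects, config.noise_sd, config.smooth_fwhm,
            config.voxel_size, rng,
        )
    return stack


def active_truth_mask(segmentation: Segmentation, effect_by_label: dict[int, float]) -> np.ndarray:
    """Ground-truth activity mask: union of structures with a nonzero effect."""
    mask = np.zeros(segmentation.labels.shape, dtype=bool)
    for lab, eff in effect_by_label.items():
        if eff != 0:
            mask |= segmentation.labels == lab
    return mask
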