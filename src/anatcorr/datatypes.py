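"""Shared in-memory containers for volumes, statistics, and correction results.

Conventions used throughout the package:

* 3D volumes are ``numpy`` arrays indexed ``(x, y, z)``; 4D subject stacks put
  the subject axis last, so ``stack[..., s]`` is subject ``s``'s volume and the
  subject axis aligns with the covariate vector.
* Voxel indices are 0-based; physical distances are derived from ``voxel_size``
  in millimetres.
* Background in a segmentation is label 0; anatomical structures carry labels
  ``>= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CovariateVector",
    "StatMap",
    "Segmentation",
    "CorrectionResult",
]


@dataclass
class CovariateVector:
    """Per-subject scalar covariate (e.g. bioimpedance fat mass), ordered to
    match the subject axis of the image stack."""

    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("covariate values must be one-dimensional")
        if len(self.subject_ids) != self.values.size:
            raise ValueError("subject_ids and values lengths differ")
        if self.values.size < 2:
            raise ValueError("a covariate needs at least 2 subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate contains non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0)


@dataclass
class StatMap:
    """A 3D statistic volume on one of three scales.

    scale ``"r"``  — Pearson correlation in [-1, 1];
    scale ``"z"``  — Gaussianized statistic (Fisher transform);
    scale ``"p"``  — p-values in (0, 1].

    ``mask`` marks voxels where the statistic is defined; values outside the
    mask are unspecified. ``n`` is the number of subjects behind the map.
    """

    values: np.ndarray
    scale: str
    mask: np.ndarray
    n: int

    _SCALES = ("r", "z", "p")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"scale must be one of {self._SCALES}")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be a 3D volume")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        masked = self.values[self.mask]
        if self.scale == "r" and masked.size and np.nanmax(np.abs(masked)) > 1 + 1e-12:
            raise ValueError("r-scale values must lie in [-1, 1] on the mask")
        if self.scale == "p" and masked.size:
            if np.nanmin(masked) <= 0 or np.nanmax(masked) > 1:
                raise ValueError("p-scale values must lie in (0, 1] on the mask")

    @property
    def masked(self) -> np.ndarray:
        """Values at masked voxels, flattened in C order."""
        return self.values[self.mask]


@dataclass
class Segmentation:
    """Integer-labelled anatomical segmentation.

    ``labels`` is a 3D integer volume with background 0; ``label_table`` maps
    each label to a structure name. The body mask is the union of all labelled
    structures. ``organ_extents`` (e_X, in voxels) and ``e_max`` drive the
    anatomy-scaled statistics.
    """

    labels: np.ndarray
    label_table: Mapping[int, str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("segmentation labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("segmentation labels must be integers")
        self.label_table = dict(self.label_table)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels present in volume but not in table: {sorted(missing)}")
        for lab in self.label_table:
            if lab <= 0:
                raise ValueError("label table may only contain positive labels")
        counts = np.bincount(self.labels.ravel())
        # a table may list structures absent from this particular volume
        # (e.g. one annotator's labelling); extents cover present labels only
        self._extents = {
            lab: int(counts[lab]) for lab in self.label_table if lab < counts.size and counts[lab] > 0
        }
        if not self._extents:
            raise ValueError("segmentation contains no labelled voxels")

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def organ_labels(self) -> list[int]:
        return sorted(self._extents)

    @property
    def organ_extents(self) -> dict[int, int]:
        """Voxel count e_X per structure."""
        return dict(self._extents)

    @property
    def e_max(self) -> int:
        """Extent of the largest structure, e_max = max_X e_X."""
        return max(self._extents.values())

    def support(self, label: int) -> np.ndarray:
        if label not in self._extents:
            raise KeyError(f"label {label} not in segmentation")
        return self.labels == label


@dataclass
class CorrectionResult:
    """Outcome of a multiple-comparison correction.

    ``level`` states the inference unit (voxel, cluster, or organ);
    ``adjusted_p`` holds one FWER-adjusted p-value per unit (for the voxel
    level, aligned with ``mask`` in C order); ``sig_mask`` broadcasts
    significance at ``alpha`` back to voxels.
    """

    level: str
    adjusted_p: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    method: str
    mask: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    # per-unit bookkeeping for cluster/organ level results
    unit_info: "object | None" = None

    _LEVELS = ("voxel", "cluster", "organ")

    def __post_init__(self) -> None:
        if self.level not in self._LEVELS:
            raise ValueError(f"level must be one of {self._LEVELS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.adjusted_p = np.asarray(self.adjusted_p, dtype=float)
        self.sig_mask = np.asarray(self.sig_mask, dtype=bool)
        if self.adjusted_p.size and (
            np.nanmin(self.adjusted_p) <= 0 or np.nanmax(self.adjusted_p) > 1
        ):
            raise ValueError("adjusted p-values must lie in (0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if np.any(self.sig_mask & ~self.mask):
                raise ValueError("sig_mask extends outside the analysis mask")

    @property
    def any_significant(self) -> bool:
        return bool(self.sig_mask.any())

    @property
    def n_significant_voxels(self) -> int:
        return int(self.sig_mask.sum())

    def p_volume(self) -> np.ndarray:
        """Adjusted p broadcast to a 3D volume (1 outside the mask/units).

        Cluster- and organ-level results store a ``unit_labels`` volume in
        ``unit_info`` (unit ``i`` marked ``i+1``); their per-unit adjusted p is
        broadcast over those supports.
        """
        if self.mask is None:
            raise ValueError("result carries no voxel mask")
        vol = np.ones(self.mask.shape, dtype=float)
        if self.level == "voxel":
            vol[self.mask] = self.adjusted_p
        elif isinstance(self.unit_info, dict) and "unit_labels" in self.unit_info:
            lab = self.unit_info["unit_labels"]
            inside = lab > 0
            vol[inside] = self.adjusted_p[lab[inside] - 1]
        return vol
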