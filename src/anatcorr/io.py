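"""File I/O: NIfTI-1 volumes, CSV covariates, TSV label tables, JSON sidecars.

Grid conventions: volumes are saved with a diagonal affine built from the
voxel size, 4D stacks put the subject axis last, and every multi-input
operation validates that grids (shape + affine) agree before computing.
Statistic scale tags (r/z/p) travel in JSON sidecars, not filenames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import CovariateVector, Segmentation, StatMap

__all__ = [
    "Volume",
    "GridError",
    "read_volume",
    "write_volume",
    "read_covariate",
    "write_covariate",
    "read_segmentation",
    "write_segmentation",
    "read_statmap",
    "write_statmap",
    "write_provenance",
]


class GridError(ValueError):
    """Inputs do not share one voxel grid."""


@dataclass
class Volume:
    """A volume plus the grid metadata needed to write it back unchanged."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_subjects(self) -> int:
        if self.data.ndim != 4:
            raise ValueError("not a 4D subject stack")
        return int(self.data.shape[-1])


def read_volume(path: str | Path) -> Volume:
    """Read a 3D/4D NIfTI-1 volume (4D: subject axis last)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D volume, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, voxel_size=zooms, affine=np.asarray(img.affine))


def write_volume(path: str | Path, data: np.ndarray,
                 voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if affine is None:
        affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms([*voxel_size] + ([1.0] if data.ndim == 4 else []))
    nib.save(img, str(path))


def check_same_grid(*volumes: Volume) -> None:
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape3 != ref.shape3:
            raise GridError(f"grid shapes differ: {v.shape3} vs {ref.shape3}")
        if not np.allclose(v.affine, ref.affine, atol=1e-6):
            raise GridError("volume orientations (affines) differ")


def read_covariate(path: str | Path, subject_order: list[str] | None = None) -> CovariateVector:
    """Read a 2-column CSV (``subject_id,value``).

    The analysis order is defined by ``subject_order`` (e.g. from a stack
    sidecar) when given — never by CSV row order alone; duplicate or missing
    subjects are errors.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"covariate CSV must have columns {sorted(required)}")
    ids = df["subject_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id in covariate file: {dupes}")
    values = df["value"].to_numpy(dtype=float)
    if subject_order is not None:
        lookup = dict(zip(ids, values))
        missing = [s for s in subject_order if s not in lookup]
        if missing:
            raise ValueError(f"subjects missing from covariate file: {missing}")
        ids = list(subject_order)
        values = np.array([lookup[s] for s in ids])
    return CovariateVector(ids, values)


def write_covariate(path: str | Path, covariate: CovariateVector) -> None:
    pd.DataFrame({"subject_id": covariate.subject_ids, "value": covariate.values}).to_csv(
        path, index=False
    )


def read_segmentation(labels_path: str | Path, table_path: str | Path) -> Segmentation:
    """Read a label volume (NIfTI) plus its label table (TSV: label, name)."""
    vol = read_volume(labels_path)
    data = np.rint(vol.data).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    if not {"label", "name"}.issubset(table.columns):
        raise ValueError("label table must have columns label and name")
    mapping = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return Segmentation(data, mapping, vol.voxel_size)


def write_segmentation(labels_path: str | Path, table_path: str | Path,
                       segmentation: Segmentation) -> None:
    write_volume(labels_path, segmentation.labels.astype(np.int16), segmentation.voxel_size)
    pd.DataFrame(
        {"label": list(segmentation.label_table), "name": list(segmentation.label_table.values())}
    ).to_csv(table_path, sep="\t", index=False)


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_statmap(path: str | Path, statmap: StatMap,
                  voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a statistic volume with a JSON sidecar carrying scale/mask info."""
    write_volume(path, statmap.values, voxel_size)
    mask_path = Path(str(path).replace(".nii", "_mask.nii", 1))
    write_volume(mask_path, statmap.mask, voxel_size)
    sidecar = {"scale": statmap.scale, "n": statmap.n, "mask_file": mask_path.name}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_statmap(path: str | Path) -> StatMap:
    meta = json.loads(_sidecar_path(path).read_text())
    vol = read_volume(path)
    mask_vol = read_volume(Path(path).parent / meta["mask_file"])
    return StatMap(values=vol.data.astype(float), scale=meta["scale"],
                   mask=mask_vol.data.astype(bool), n=int(meta["n"]))


def write_provenance(path: str | Path, record: dict) -> None:
    """Write a JSON provenance sidecar (config, seeds, package versions)."""
    import scipy

    from . import __version__

    full = dict(record)
    full.setdefault("versions", {})
    full["versions"].update(
        {"anatcorr": __version__, "numpy": np.__version__,
         "scipy": scipy.__version__, "nibabel": nib.__version__}
    )
    Path(path).write_text(json.dumps(full, indent=2, default=str))
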