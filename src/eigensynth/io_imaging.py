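"""NIfTI ingestion and the flattened subjects-by-voxels matrix.

The whole pipeline operates on a ``VoxelDataset``: a K x N float64 matrix
(K subjects, N in-mask voxels), the class label of each subject, and the
geometry needed to put a row back into a 3D volume. Volumes are assumed
spatially co-registered (same shape and affine); registration itself is out
of scope here.

Voxel linearization order is fixed: C order (last axis fastest) over the
true voxels of the mask, i.e. ``volume[mask]`` with a C-contiguous boolean
mask. The order is deterministic, so two reads of the same files produce
bit-identical matrices and serialized models remain portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGeometry",
    "VoxelDataset",
    "GeometryError",
    "LabelingError",
    "read_dataset",
    "flatten",
    "unflatten",
    "write_volume",
]

#: relative tolerance for declaring two affines "the same registration"
AFFINE_RTOL = 1e-4


class GeometryError(ValueError):
    """Volume shapes/affines are inconsistent or do not match the geometry."""


class LabelingError(ValueError):
    """An image has no label row, or a label row points at no image."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape and voxel-to-world mapping shared by all volumes of a dataset."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_units: str = "mm"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GeometryError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGeometry") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, rtol=AFFINE_RTOL, atol=1e-8
        )


@dataclass
class VoxelDataset:
    """K subjects x N in-mask voxels with labels, mask and geometry.

    ``data`` holds intensities in normalized arbitrary units, float64,
    finite everywhere. ``mask`` is a C-contiguous boolean volume whose true
    count equals N.
    """

    data: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    geometry: VolumeGeometry
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D subjects x voxels matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per subject")
        self.mask = np.ascontiguousarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise GeometryError("mask shape does not match geometry")
        if int(self.mask.sum()) != self.data.shape[1]:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} true voxels"
            )
        if self.subject_ids is None:
            self.subject_ids = np.array([f"sub-{i:04d}" for i in range(len(self.labels))])
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
            if self.subject_ids.shape != self.labels.shape:
                raise ValueError("subject_ids must match labels in length")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def classes(self) -> list:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def class_rows(self, class_id) -> np.ndarray:
        """Row indices of the subjects belonging to ``class_id``."""
        idx = np.flatnonzero(self.labels == class_id)
        if idx.size == 0:
            raise KeyError(f"no subjects with class {class_id!r}")
        return idx

    def subset(self, rows: np.ndarray) -> "VoxelDataset":
        rows = np.asarray(rows)
        return VoxelDataset(
            data=self.data[rows],
            labels=self.labels[rows],
            mask=self.mask,
            geometry=self.geometry,
            subject_ids=self.subject_ids[rows],
        )

    def volume(self, row: int) -> np.ndarray:
        return unflatten(self.data[row], self.mask, self.geometry)


def flatten(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract in-mask voxels of a 3D volume in the canonical C order."""
    volume = np.asarray(volume)
    mask = np.ascontiguousarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise GeometryError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    return np.ascontiguousarray(volume)[mask].astype(np.float64)


def unflatten(row: np.ndarray, mask: np.ndarray, geometry: VolumeGeometry) -> np.ndarray:
    """Place a flat row back into a volume; out-of-mask voxels are 0."""
    mask = np.ascontiguousarray(mask, dtype=bool)
    if mask.shape != geometry.shape:
        raise GeometryError("mask shape does not match geometry")
    row = np.asarray(row, dtype=np.float64).ravel()
    n = int(mask.sum())
    if row.size != n:
        raise ValueError(f"row has length {row.size} but mask has {n} true voxels")
    vol = np.zeros(geometry.shape, dtype=np.float64)
    vol[mask] = row
    return vol


def write_volume(volume: np.ndarray, geometry: VolumeGeometry, path) -> None:
    """Write a volume as NIfTI-1, float32 on disk (float64 in memory)."""
    volume = np.asarray(volume)
    if volume.shape != geometry.shape:
        raise GeometryError(
            f"volume shape {volume.shape} does not match geometry {geometry.shape}"
        )
    img = nib.Nifti1Image(volume.astype(np.float32), geometry.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _load_volume(path) -> tuple[np.ndarray, VolumeGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    geom = VolumeGeometry(shape=data.shape, affine=np.asarray(img.affine, dtype=float))
    return data, geom


def read_dataset(image_paths=None, label_table=None, mask=None) -> VoxelDataset:
    """Read co-registered NIfTI volumes plus a label table into a VoxelDataset.

    Parameters
    ----------
    image_paths
        Paths of the NIfTI volumes. May be omitted, in which case the
        ``path`` column of the label table is used.
    label_table
        CSV/TSV file with header columns ``subject_id,path,class`` — one
        row per image.
    mask
        Optional NIfTI binary mask. When absent, the implicit mask keeps
        every voxel that is strictly positive in at least one subject
        (PET/SPECT background is zero or near-zero).
    """
    if label_table is None:
        raise LabelingError("a label table (subject_id,path,class) is required")
    table_path = Path(label_table)
    sep = "\t" if table_path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(table_path, sep=sep)
    required = {"subject_id", "path", "class"}
    if not required.issubset(table.columns):
        raise LabelingError(
            f"label table must have columns {sorted(required)}, got {list(table.columns)}"
        )

    if image_paths is None:
        image_paths = [table_path.parent / p if not Path(p).is_absolute() else Path(p)
                       for p in table["path"]]
    image_paths = [Path(p) for p in image_paths]

    by_name: dict[str, pd.Series] = {}
    for _, row in table.iterrows():
        by_name[Path(row["path"]).name] = row

    volumes = []
    labels = []
    subject_ids = []
    geometry: VolumeGeometry | None = None
    for path in image_paths:
        data, geom = _load_volume(path)
        if geometry is None:
            geometry = geom
        elif not geometry.matches(geom):
            raise GeometryError(
                f"{path}: shape/affine {geom.shape} does not match the first "
                f"volume's geometry {geometry.shape}"
            )
        row = by_name.get(path.name)
        if row is None:
            raise LabelingError(f"no label-table row for image {path}")
        volumes.append(data)
        labels.append(row["class"])
        subject_ids.append(str(row["subject_id"]))
    assert geometry is not None

    stack = np.stack(volumes)  # K x shape
    if mask is not None:
        mask_data, mask_geom = _load_volume(mask)
        if not geometry.matches(mask_geom):
            raise GeometryError(f"{mask}: mask geometry does not match the volumes")
        mask_arr = mask_data > 0
    else:
        # implicit mask: strictly positive in at least one subject
        mask_arr = (stack > 0).any(axis=0)

    data = stack.reshape(len(volumes), -1)[:, mask_arr.ravel()]
    return VoxelDataset(
        data=data,
        labels=np.asarray(labels, dtype=object),
        mask=mask_arr,
        geometry=geometry,
        subject_ids=np.asarray(subject_ids, dtype=object),
    )
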