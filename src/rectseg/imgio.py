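"""NIfTI volume and cohort-manifest I/O.

This module is the single source of truth for the spatial data model.  A
:class:`VolumeGrid` is a 3D scalar image on a regular lattice with voxel
spacing in millimetres; a :class:`SegMask` is a binary mask on the same kind
of lattice.  Conventions, fixed once and used everywhere downstream:

* arrays are indexed ``(x, y, z)`` with 0-based indices,
* the world frame is RAS, and the world coordinate of voxel ``i`` is
  ``origin + i * spacing``,
* spacing is strictly positive per axis; anisotropy (e.g. 3 mm CT slice
  thickness) is carried explicitly, never assumed away.

Label maps are read as integer grids; turning a label map into a binary mask
is an explicit preprocessing operation, never implicit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "SegMask",
    "SubjectRecord",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

Sex = Literal["male", "female"]
Diagnosis = Literal["prostate", "cervical"]

#: Manifest CSV schema (the ``fold`` column is optional on read).
MANIFEST_COLUMNS = [
    "subject_id",
    "sex",
    "diagnosis",
    "image_path",
    "label_path",
    "true_rectum_volume_cm3",
    "split",
    "fold",
]

_SEX_DIAGNOSIS = {"male": "prostate", "female": "cervical"}


@dataclass
class VolumeGrid:
    """A 3D scalar image with explicit geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (CT intensities in HU, or integer labels).
    spacing : tuple of float
        Voxel edge length per axis, in mm.  Strictly positive.
    origin : tuple of float
        World (RAS, mm) coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"non-3D image: got {self.values.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing: {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, rtol: float = 1e-5) -> bool:
        s = np.asarray(self.spacing)
        return bool(np.all(np.abs(s - s[0]) <= rtol * s[0]))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return replace(self, values=values)


@dataclass
class SegMask(VolumeGrid):
    """Binary mask on a :class:`VolumeGrid` lattice (values in {0, 1})."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("SegMask values must be binary (0/1)")
            self.values = self.values.astype(bool)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


@dataclass
class SubjectRecord:
    """One cohort subject: identity, cohort stratum, files, ground truth."""

    subject_id: str
    sex: Sex
    diagnosis: Diagnosis
    image_path: str
    label_path: str
    true_rectum_volume_cm3: float
    split: Optional[str] = None
    fold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex value: {self.sex!r}")
        expected = _SEX_DIAGNOSIS[self.sex]
        if self.diagnosis != expected:
            raise ValueError(
                f"sex/diagnosis pairing violation for {self.subject_id}: "
                f"sex={self.sex} requires diagnosis={expected}, got {self.diagnosis}"
            )
        if self.split not in (None, "", "train", "val", "test"):
            raise ValueError(f"unknown split value: {self.split!r}")
        if self.split == "":
            self.split = None


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(affine: np.ndarray):
    rot = affine[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive spacing in affine: {spacing}")
    origin = affine[:3, 3]
    return tuple(float(s) for s in spacing), tuple(float(o) for o in origin)


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI file as a :class:`VolumeGrid`.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the image is not 3D or carries a non-positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"unreadable file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    spacing, origin = _geometry_from_affine(img.affine)
    return VolumeGrid(values=data, spacing=spacing, origin=origin)


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` (or mask) to NIfTI-1.

    Float data is stored as float32, integer labels as uint8, boolean masks
    as uint8 {0,1}; the affine encodes spacing and origin (RAS).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    elif np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.uint8)
    else:
        values = values.astype(np.float32)
    img = nib.Nifti1Image(values, _affine_from_geometry(grid.spacing, grid.origin))
    nib.save(img, str(path))


def read_manifest(path) -> list[SubjectRecord]:
    """Read a cohort manifest CSV; validates sex/diagnosis pairing per row."""
    path = Path(path)
    records: list[SubjectRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        required = set(MANIFEST_COLUMNS) - {"fold", "split"}
        missing = required - set(fields)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            if not row.get("image_path") or not row.get("label_path"):
                raise ValueError(f"missing file path in manifest row: {row}")
            fold_raw = row.get("fold", "")
            fold = int(fold_raw) if fold_raw not in (None, "") else None
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    sex=row["sex"],  # type: ignore[arg-type]
                    diagnosis=row["diagnosis"],  # type: ignore[arg-type]
                    image_path=row["image_path"],
                    label_path=row["label_path"],
                    true_rectum_volume_cm3=float(row["true_rectum_volume_cm3"]),
                    split=row.get("split") or None,
                    fold=fold,
                )
            )
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in manifest")
    return records


def write_manifest(records: Sequence[SubjectRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.sex,
                    r.diagnosis,
                    r.image_path,
                    r.label_path,
                    repr(float(r.true_rectum_volume_cm3)),
                    r.split or "",
                    "" if r.fold is None else r.fold,
                ]
            )
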