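"""Core 3D image grid model, file I/O and mask algebra.

Every stage of the pipeline exchanges data as axis-aligned 3D scalar grids
(:class:`VolumeImage`), binary voxel masks (:class:`BinaryMask`) and dense
displacement fields (:class:`DisplacementField`).  World coordinates follow
``world = origin + index * spacing`` with 0-based voxel indices; oblique
orientations (non-identity direction cosines) are deliberately unsupported
and rejected at read time.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ValueKind",
    "VolumeImage",
    "BinaryMask",
    "LabelMap",
    "DisplacementField",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "mask_volume_ml",
    "mask_ops",
    "warp_mask_nn",
]

_GRID_ATOL_MM = 1e-6


class ValueKind(str, enum.Enum):
    """Physical meaning of the scalar values stored on a grid."""

    HU = "hu"
    DOSE = "dose"
    PROBABILITY = "probability"


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


def _check_grid3(shape) -> None:
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"expected a 3D grid with positive dims, got shape {tuple(shape)}")


@dataclass
class VolumeImage:
    """A 3D scalar grid with millimetre spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; semantics given by ``value_kind`` (HU, Gy, or a
        probability in [0, 1]).
    spacing : tuple of 3 floats
        Voxel edge lengths in mm, all strictly positive.
    origin : tuple of 3 floats
        World position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_kind: ValueKind = ValueKind.HU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid3(self.data.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.value_kind = ValueKind(self.value_kind)
        if self.value_kind is ValueKind.PROBABILITY:
            lo, hi = float(np.min(self.data)), float(np.max(self.data))
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"probability volume has values outside [0, 1] (range [{lo}, {hi}])"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GRID_ATOL_MM)
            and np.allclose(self.origin, other.origin, atol=_GRID_ATOL_MM)
        )

    def like(self, data: np.ndarray, value_kind: ValueKind | None = None) -> "VolumeImage":
        """New volume on this grid carrying ``data``."""
        return VolumeImage(data, self.spacing, self.origin, value_kind or self.value_kind)


@dataclass
class BinaryMask:
    """A {0,1} voxel mask aligned to a :class:`VolumeImage` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        _check_grid3(arr.shape)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other) -> bool:
        return VolumeImage.same_grid(self, other)  # type: ignore[arg-type]

    def like(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(data).astype(bool), self.spacing, self.origin)

    @classmethod
    def from_image(cls, image: VolumeImage, data: np.ndarray) -> "BinaryMask":
        return cls(np.asarray(data).astype(bool), image.spacing, image.origin)


@dataclass
class LabelMap:
    """Integer-labelled voxel map with a legend mapping label -> name."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        _check_grid3(arr.shape)
        self.data = arr.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return VolumeImage.same_grid(self, other)  # type: ignore[arg-type]

    def mask_of(self, label: int | str) -> BinaryMask:
        if isinstance(label, str):
            inv = {v: k for k, v in self.names.items()}
            label = inv[label]
        return BinaryMask((self.data == int(label)).astype(np.uint8), self.spacing, self.origin)


@dataclass
class DisplacementField:
    """Dense displacement field, mm, mapping pre-frame voxels to post positions.

    ``data`` has shape (nx, ny, nz, 3): for the voxel at world position x in
    the pre-RT frame, x + data[i, j, k] is the corresponding position in the
    post-RT frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"field must have shape (nx,ny,nz,3), got {self.data.shape}")
        _check_grid3(self.data.shape[:3])
        if not np.isfinite(self.data).all():
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def same_grid(self, other) -> bool:
        return (
            self.shape == (other.shape if isinstance(other.shape, tuple) else tuple(other.shape))
            and np.allclose(self.spacing, other.spacing, atol=_GRID_ATOL_MM)
            and np.allclose(self.origin, other.origin, atol=_GRID_ATOL_MM)
        )


# ---------------------------------------------------------------------------
# File I/O.  NIfTI through nibabel, MetaImage through SimpleITK.  Only
# axis-aligned (identity direction cosine) files are accepted.
# ---------------------------------------------------------------------------

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _has_ext(path: str, exts) -> bool:
    p = str(path).lower()
    return any(p.endswith(e) for e in exts)


def _read_raw(path) -> tuple[np.ndarray, tuple, tuple]:
    """Return (array, spacing, origin) with axes ordered (x, y, z[, vec])."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if _has_ext(path, _NIFTI_EXT):
        img = nib.load(path)
        aff = img.affine
        rot = aff[:3, :3]
        spacing = np.sqrt((rot**2).sum(axis=0))
        if not np.allclose(rot, np.diag(spacing), atol=1e-4):
            raise ValueError(f"{path}: non-axis-aligned orientation is not supported")
        arr = np.asarray(img.dataobj)
        origin = tuple(aff[:3, 3])
        return arr, tuple(spacing), origin
    if _has_ext(path, _META_EXT):
        img = sitk.ReadImage(path)
        if not np.allclose(np.asarray(img.GetDirection()).reshape(3, 3), np.eye(3), atol=1e-4):
            raise ValueError(f"{path}: non-identity direction cosines are not supported")
        arr = sitk.GetArrayFromImage(img)  # (z, y, x[, vec])
        if arr.ndim == 3:
            arr = arr.transpose(2, 1, 0)
        elif arr.ndim == 4:
            arr = arr.transpose(2, 1, 0, 3)
        return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    raise IOError(f"unsupported file format: {path} (expected .nii/.nii.gz/.mha/.mhd)")


def _write_raw(path, arr: np.ndarray, spacing, origin) -> None:
    path = os.fspath(path)
    if _has_ext(path, _NIFTI_EXT):
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = origin
        nib.save(nib.Nifti1Image(arr, aff), path)
    elif _has_ext(path, _META_EXT):
        if arr.ndim == 3:
            img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        else:
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(arr.transpose(2, 1, 0, 3)), isVector=True
            )
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, path)
    else:
        raise IOError(f"unsupported file format: {path}")


def read_volume(path, expected_kind: ValueKind | str = ValueKind.HU) -> VolumeImage:
    """Read a scalar volume; the caller declares what its values mean.

    Raises on 2D/4D data and on probability volumes with out-of-range values.
    """
    arr, spacing, origin = _read_raw(path)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 3D scalar data, got {arr.ndim}D")
    return VolumeImage(np.asarray(arr, dtype=np.float64), spacing, origin, ValueKind(expected_kind))


def write_volume(image: VolumeImage, path) -> None:
    _write_raw(path, np.asarray(image.data, dtype=np.float32), image.spacing, image.origin)


def read_mask(path) -> BinaryMask:
    arr, spacing, origin = _read_raw(path)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask data, got {arr.ndim}D")
    return BinaryMask(np.rint(arr).astype(np.uint8), spacing, origin)


def write_mask(mask: BinaryMask, path) -> None:
    _write_raw(path, mask.data.astype(np.uint8), mask.spacing, mask.origin)


def read_field(path) -> DisplacementField:
    arr, spacing, origin = _read_raw(path)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected (nx,ny,nz,3) displacement data, got {arr.shape}")
    return DisplacementField(arr, spacing, origin)


def write_field(field: DisplacementField, path) -> None:
    _write_raw(path, np.asarray(field.data, dtype=np.float32), field.spacing, field.origin)


# ---------------------------------------------------------------------------
# Mask algebra
# ---------------------------------------------------------------------------


def mask_volume_ml(mask: BinaryMask) -> float:
    """Volume of the mask in millilitres: voxel count x voxel size / 1000."""
    return mask.count() * float(np.prod(mask.spacing)) / 1000.0


def mask_ops(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxelwise set operation on two grid-aligned masks.

    ``op`` is one of ``union``, ``intersect``, ``subtract`` (a AND NOT b).
    """
    if not a.same_grid(b):
        raise GridMismatchError("mask grids differ (shape/spacing/origin)")
    if op == "union":
        out = a.data | b.data
    elif op == "intersect":
        out = a.data & b.data
    elif op == "subtract":
        out = a.data & ~b.data
    else:
        raise ValueError(f"unknown op {op!r}; expected union/intersect/subtract")
    return a.like(out)


def warp_mask_nn(mask: BinaryMask, fld: DisplacementField) -> BinaryMask:
    """Resample ``mask`` into the field's frame with nearest-neighbour lookup.

    For each output voxel x the input mask is sampled at x + u(x) (mm);
    samples falling outside the input grid map to 0.  The output lives on
    the field's grid.
    """
    if not np.allclose(fld.spacing, mask.spacing, atol=_GRID_ATOL_MM):
        raise GridMismatchError("field and mask spacing differ")
    sp = np.asarray(fld.spacing)
    shape = fld.shape
    idx = np.indices(shape, dtype=float)
    world = idx * sp.reshape(3, 1, 1, 1) + np.asarray(fld.origin).reshape(3, 1, 1, 1)
    target = world + np.moveaxis(fld.data, -1, 0)
    src_idx = (target - np.asarray(mask.origin).reshape(3, 1, 1, 1)) / sp.reshape(3, 1, 1, 1)
    out = ndimage.map_coordinates(
        mask.data.astype(np.uint8), src_idx, order=0, mode="constant", cval=0
    )
    return BinaryMask(out.astype(bool), fld.spacing, fld.origin)
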