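"""Core domain types, NIfTI I/O and the Dice overlap metric.

Axes convention
---------------
All 3-D arrays in this package are indexed ``(z, y, x)`` where ``z`` is the
slice index of an axial acquisition and ``(y, x)`` are the in-plane axes.
Voxel spacing is carried as ``(dx, dy, dz)`` in millimetres, i.e. in the
*reverse* order of the array axes, matching the way scanner metadata is
usually quoted (in-plane resolution first, slice thickness last).  NIfTI
files store data ``(x, y, z)``; the readers and writers below transpose so
that in-memory arrays always follow the package convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LabelMask",
    "RegionLabel",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "dice_coefficient",
]


class RegionLabel(str, Enum):
    """The four bone-marrow volumes of interest."""

    SPINE = "spine"
    FEMORAL_HEAD = "femoral_head"
    TOTAL_HIP = "total_hip"
    DIAPHYSIS = "diaphysis"


def _validate_geometry(data: np.ndarray, spacing) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components (dx, dy, dz), got {spacing}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be > 0, got {spacing}")


@dataclass
class Volume3D:
    """A 3-D scalar grid with voxel spacing.

    Parameters
    ----------
    data
        Real-valued array indexed ``(z, y, x)``.
    spacing
        Voxel size ``(dx, dy, dz)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.2, 2.2, 4.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        _validate_geometry(self.data, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axial_slice(self, k: int) -> np.ndarray:
        """The 2-D in-plane sub-grid at slice index ``z = k``."""
        return self.data[k]

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class LabelMask:
    """A binary 3-D mask aligned to a companion :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.2, 2.2, 4.5)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        _validate_geometry(self.data, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return self.voxel_count * dx * dy * dz

    def centre_of_mass(self) -> np.ndarray:
        """Voxel-count-weighted mean index, ordered ``(z, y, x)``.

        Raises
        ------
        ValueError
            If the mask is empty (the centre of mass is undefined).
        """
        if self.voxel_count == 0:
            raise ValueError("centre of mass is undefined for an empty mask")
        idx = np.argwhere(self.data > 0)
        return idx.mean(axis=0)


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, file contains a {data.ndim}-D array"
        )
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing in header: {zooms}")
    # NIfTI arrays are (x, y, z); package convention is (z, y, x).
    return np.transpose(data, (2, 1, 0)), (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def read_volume(path) -> Volume3D:
    """Read a scalar volume from a NIfTI file (``.nii``/``.nii.gz``)."""
    data, spacing = _load_nifti(path)
    return Volume3D(data.astype(float), spacing)


def read_mask(path) -> LabelMask:
    """Read a binary mask from a NIfTI file."""
    data, spacing = _load_nifti(path)
    return LabelMask((data > 0).astype(np.uint8), spacing)


def _write_nifti(data: np.ndarray, spacing, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    dx, dy, dz = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume to NIfTI; ``read_volume`` round-trips data and spacing."""
    _write_nifti(vol.data.astype(np.float64), vol.spacing, path)


def write_mask(mask: LabelMask, path) -> None:
    """Write a binary mask to NIfTI as unsigned 8-bit."""
    _write_nifti(mask.data.astype(np.uint8), mask.spacing, path)


def dice_coefficient(a: LabelMask, b: LabelMask) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)`` between two binary masks.

    Symmetric in its arguments.  Two empty masks are identical sets and
    score 1.0; one empty mask against a non-empty one scores 0.0.
    """
    da = a.data if isinstance(a, LabelMask) else np.asarray(a)
    db = b.data if isinstance(b, LabelMask) else np.asarray(b)
    if da.shape != db.shape:
        raise ValueError(f"mask shapes differ: {da.shape} vs {db.shape}")
    na = int(da.sum())
    nb = int(db.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(da > 0, db > 0).sum())
    return 2.0 * inter / (na + nb)
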