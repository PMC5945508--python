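"""Core grid types and volume/mask I/O.

An :class:`SUVVolume` is a 3-D scalar grid of standardized uptake values
(SUV, dimensionless) on a regular anisotropic grid.  Axis order is fixed
as (x, y, z) everywhere in this package, with ``spacing`` in millimetres
per voxel stored in the same order; grid indexing is 0-based.  Masks are
boolean grids aligned voxel-for-voxel with their companion volume.

I/O goes through SimpleITK, which supports both NIfTI (``.nii``,
``.nii.gz``) and NRRD (``.nrrd``).  SimpleITK stores arrays as (z, y, x);
the reader and writer transpose so that the in-memory convention is
(x, y, z) end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np
import SimpleITK as sitk

__all__ = [
    "SUVVolume",
    "RegionMask",
    "MaskStatistics",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_statistics",
    "EmptyRegionError",
    "VolumeFormatError",
]


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3-D scalar volume."""


class EmptyRegionError(ValueError):
    """Raised when an operation requires a non-empty voxel region."""


Triplet = Tuple[float, float, float]


@dataclass(frozen=True)
class SUVVolume:
    """A 3-D SUV image with physical voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV per voxel; finite and non-negative.
    spacing : (float, float, float)
        Voxel size in mm along (x, y, z); strictly positive.
    origin : (float, float, float)
        World-coordinate offset of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: Triplet
    origin: Triplet = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise VolumeFormatError(
                f"SUV volume must be 3-D, got {values.ndim}-D"
            )
        if values.size == 0:
            raise VolumeFormatError("SUV volume must have at least one voxel")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must be finite")
        if values.min() < 0:
            raise ValueError("SUV values must be >= 0")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "SUVVolume":
        """Same geometry, new voxel values."""
        return SUVVolume(values=values, spacing=self.spacing, origin=self.origin)


@dataclass(frozen=True)
class RegionMask:
    """Boolean VOI mask aligned to a companion volume (same shape)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags)
        if flags.ndim != 3:
            raise VolumeFormatError(f"mask must be 3-D, got {flags.ndim}-D")
        object.__setattr__(self, "flags", flags.astype(bool))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.flags.shape

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.flags & other.flags)

    def __or__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.flags | other.flags)


@dataclass(frozen=True)
class MaskStatistics:
    count: int
    min: float
    max: float
    mean: float
    sum: float = field(default=float("nan"))


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format {path.name!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path) -> SUVVolume:
    """Read a NIfTI or NRRD scalar volume into an :class:`SUVVolume`.

    Spacing and origin are taken from the file header; voxel values are
    passed through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK message passthrough
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if image.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path.name}: expected a 3-D volume, got {image.GetDimension()}-D"
        )
    # GetArrayFromImage returns (z, y, x); transpose to (x, y, z).
    values = sitk.GetArrayFromImage(image).transpose(2, 1, 0)
    return SUVVolume(
        values=values,
        spacing=tuple(image.GetSpacing()),
        origin=tuple(image.GetOrigin()),
    )


def write_volume(volume: SUVVolume, path) -> None:
    """Write a volume as NIfTI or NRRD (chosen by file suffix)."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    image = sitk.GetImageFromArray(volume.values.transpose(2, 1, 0))
    image.SetSpacing(volume.spacing)
    image.SetOrigin(volume.origin)
    sitk.WriteImage(image, str(path))


def write_mask(mask: RegionMask, spacing: Triplet, path, origin: Triplet = (0.0, 0.0, 0.0)) -> None:
    """Persist a mask as an 8-bit 0/1 volume in the same formats as images."""
    path = Path(path)
    _check_suffix(path)
    image = sitk.GetImageFromArray(mask.flags.astype(np.uint8).transpose(2, 1, 0))
    image.SetSpacing(tuple(float(s) for s in spacing))
    image.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(image, str(path))


def read_mask(path) -> RegionMask:
    """Read a 0/1 volume back as a boolean mask (any nonzero voxel is in)."""
    volume = read_volume(path)
    return RegionMask(volume.values > 0.5)


def mask_statistics(volume: SUVVolume, mask: RegionMask) -> MaskStatistics:
    """Count/min/max/mean of SUV inside a non-empty mask."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: volume {volume.shape} vs mask {mask.shape}"
        )
    inside = volume.values[mask.flags]
    if inside.size == 0:
        raise EmptyRegionError("mask selects no voxels")
    return MaskStatistics(
        count=int(inside.size),
        min=float(inside.min()),
        max=float(inside.max()),
        mean=float(inside.mean()),
        sum=float(inside.sum()),
    )
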