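"""Contrast-oriented adaptive threshold tumor delineation.

The tumor VOI is the 26-connected set of voxels, containing the hottest
voxel of a user-supplied search region, whose uptake strictly exceeds

    T = beta * I70 + Ibgd

where ``I70`` is the mean uptake over the connected 70%-of-maximum core
contour and ``Ibgd`` is the mean background uptake in a shell 2 voxels
thick located 6 voxels outside that core, restricted to voxels below
2.5 SUV.  ``beta`` defaults to 0.3.  Shell distance is counted in
binary-dilation steps with a full 3x3x3 structuring element (Chebyshev
voxel distance); both thresholds use strict ``>`` so ties are excluded.

The search region stands in for the operator's visual choice of the
tumor; it bounds the maximum search so that a hot spot elsewhere in the
field of view cannot capture the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import EmptyRegionError, RegionMask, SUVVolume

__all__ = [
    "SegmentationParams",
    "SegmentationError",
    "DegenerateInputError",
    "BackgroundUndefinedError",
    "core_region",
    "i70",
    "i_bgd",
    "threshold_value",
    "segment_tumor",
    "dice",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when the adaptive threshold produces an empty VOI."""


class DegenerateInputError(SegmentationError):
    """Raised when the 70% core contour is empty (e.g. constant input)."""


class BackgroundUndefinedError(SegmentationError):
    """Raised when no shell voxel lies below the background cap."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the contrast-oriented algorithm.

    Defaults follow the calibrated configuration: ``beta = 0.3``, core
    contour at 70% of the maximum, a background shell 2 voxels thick at
    a 6-voxel gap, and a 2.5-SUV cap on shell voxels (the cap never
    applies to the VOI itself).
    """

    beta: float = 0.3
    core_fraction: float = 0.70
    shell_thickness: int = 2
    shell_gap: int = 6
    background_cap: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if not 0 < self.core_fraction < 1:
            raise ValueError("core fraction must be in (0, 1)")
        if self.shell_thickness < 1 or self.shell_gap < 1:
            raise ValueError("shell thickness and gap must be >= 1")
        if self.background_cap <= 0:
            raise ValueError("background cap must be > 0")


def _component_containing_max(
    candidates: np.ndarray, volume: SUVVolume, search: RegionMask
) -> np.ndarray:
    """26-connected component of ``candidates`` holding the search max."""
    labels, _ = ndimage.label(candidates, structure=_STRUCTURE_26)
    masked = np.where(search.flags, volume.values, -np.inf)
    max_index = np.unravel_index(int(np.argmax(masked)), volume.shape)
    label_at_max = labels[max_index]
    if label_at_max == 0:
        return np.zeros_like(candidates)
    return labels == label_at_max


def core_region(
    volume: SUVVolume, search: RegionMask, core_fraction: float = 0.70
) -> RegionMask:
    """Connected supra-70% core contour containing the hottest voxel."""
    if volume.shape != search.shape:
        raise ValueError("volume and search region shapes differ")
    if search.count == 0:
        raise EmptyRegionError("search region is empty")
    inside = volume.values[search.flags]
    vmax = float(inside.max())
    if vmax == float(inside.min()):
        raise DegenerateInputError(
            "search region has no contrast (constant uptake)"
        )
    candidates = search.flags & (volume.values > core_fraction * vmax)
    if not candidates.any():
        raise DegenerateInputError(
            "no voxel strictly exceeds the core fraction of the maximum"
        )
    return RegionMask(_component_containing_max(candidates, volume, search))


def i70(volume: SUVVolume, search: RegionMask, core_fraction: float = 0.70) -> float:
    """Mean uptake over the 70%-of-maximum core contour."""
    core = core_region(volume, search, core_fraction)
    return float(volume.values[core.flags].mean())


def shell_mask(core: RegionMask, gap: int, thickness: int) -> RegionMask:
    """Voxels at Chebyshev distance in (gap, gap + thickness] from the core."""
    inner = ndimage.binary_dilation(core.flags, _STRUCTURE_26, iterations=gap)
    outer = ndimage.binary_dilation(
        core.flags, _STRUCTURE_26, iterations=gap + thickness
    )
    return RegionMask(outer & ~inner)


def i_bgd(
    volume: SUVVolume, core: RegionMask, params: SegmentationParams = SegmentationParams()
) -> float:
    """Mean background uptake in the sub-cap portion of the shell."""
    if core.count == 0:
        raise EmptyRegionError("core region is empty")
    shell = shell_mask(core, params.shell_gap, params.shell_thickness)
    eligible = shell.flags & (volume.values < params.background_cap)
    if not eligible.any():
        raise BackgroundUndefinedError(
            f"no shell voxel below the {params.background_cap} SUV cap"
        )
    return float(volume.values[eligible].mean())


def threshold_value(
    volume: SUVVolume, search: RegionMask, params: SegmentationParams = SegmentationParams()
) -> float:
    """The adaptive threshold T = beta * I70 + Ibgd."""
    core = core_region(volume, search, params.core_fraction)
    i70_value = float(volume.values[core.flags].mean())
    return params.beta * i70_value + i_bgd(volume, core, params)


def segment_tumor(
    volume: SUVVolume, search: RegionMask, params: SegmentationParams = SegmentationParams()
) -> RegionMask:
    """Delineate the tumor VOI by the contrast-oriented threshold."""
    t = threshold_value(volume, search, params)
    candidates = search.flags & (volume.values > t)
    voi = _component_containing_max(candidates, volume, search)
    if not voi.any():
        raise SegmentationError(f"threshold T = {t:.3f} SUV leaves an empty VOI")
    return RegionMask(voi)


def dice(a: RegionMask, b: RegionMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|)."""
    denom = a.count + b.count
    if denom == 0:
        raise EmptyRegionError("both masks are empty")
    return 2.0 * (a & b).count / denom
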