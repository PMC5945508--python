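"""Fixed-bound (absolute) intensity discretization.

VOI voxel intensities are mapped to integer gray levels by

    R(x) = round[ bins * (I(x) - lower) / (upper - lower) ]

with fixed bounds shared across all lesions (defaults 0 and 25 SUV),
then clamped to [1, bins].  Fixed bounds make the bin width an absolute
SUV quantity — 25/64 ≈ 0.4 SUV at the default 64 bins, 3.1 at 8 bins,
0.1 at 256 bins — so discretization does not depend on each lesion's
own intensity range (a per-lesion min–max rescaling couples texture
values to tumor volume and is deliberately not offered here).

Rounding is half-away-from-zero, stated explicitly because banker's
rounding would change isolated levels.  The raw formula can produce
level 0 for intensities within half a bin of the lower bound; those are
merged into level 1 so levels index 1-based texture matrices.
Intensities outside the bounds are clipped first and the clipped-voxel
count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .volumes import EmptyRegionError, RegionMask, SUVVolume

__all__ = ["DiscretizationConfig", "GrayLevelVolume", "discretize", "bin_width"]

#: Sentinel level for voxels outside the VOI; excluded from all matrices.
OUTSIDE = 0


@dataclass(frozen=True)
class DiscretizationConfig:
    """Absolute-resampling bounds and bin count."""

    lower: float = 0.0
    upper: float = 25.0
    bins: int = 64

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.bins < 2:
            raise ValueError("need at least 2 bins")


@dataclass(frozen=True)
class GrayLevelVolume:
    """Integer gray levels on the full grid; in-mask levels in 1..bins.

    ``levels`` carries the sentinel 0 outside the mask.  ``n_clipped``
    counts in-mask voxels whose intensity fell outside the bounds.
    """

    levels: np.ndarray
    config: DiscretizationConfig
    mask: RegionMask
    n_clipped: int = 0

    def __post_init__(self) -> None:
        inside = self.levels[self.mask.flags]
        if inside.size and (inside.min() < 1 or inside.max() > self.config.bins):
            raise ValueError("in-mask levels must lie in [1, bins]")

    @property
    def masked_levels(self) -> np.ndarray:
        """Flat array of in-mask levels."""
        return self.levels[self.mask.flags]

    def bin_center(self, level: np.ndarray) -> np.ndarray:
        """SUV at the center of a level's bin (for reconstruction)."""
        width = bin_width(self.config)
        return self.config.lower + (np.asarray(level) - 0.5) * width


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # values here are always >= 0, so half-away == floor(x + 0.5)
    return np.floor(x + 0.5)


def discretize(
    volume: SUVVolume, mask: RegionMask, config: DiscretizationConfig = DiscretizationConfig()
) -> GrayLevelVolume:
    """Discretize in-mask intensities to gray levels 1..bins."""
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if mask.count == 0:
        raise EmptyRegionError("mask is empty")
    inside = volume.values[mask.flags]
    n_clipped = int(((inside < config.lower) | (inside > config.upper)).sum())
    clipped = np.clip(inside, config.lower, config.upper)
    raw = _round_half_away(
        config.bins * (clipped - config.lower) / (config.upper - config.lower)
    )
    levels_in = np.clip(raw, 1, config.bins).astype(np.int32)
    levels = np.full(volume.shape, OUTSIDE, dtype=np.int32)
    levels[mask.flags] = levels_in
    return GrayLevelVolume(levels=levels, config=config, mask=mask, n_clipped=n_clipped)


def bin_width(config: DiscretizationConfig) -> float:
    """Absolute bin width in SUV: (upper - lower) / bins."""
    return (config.upper - config.lower) / config.bins
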