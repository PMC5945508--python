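"""Radiomic feature extraction: conventional, histogram, GLCM, GLRLM.

Eight features are measured per VOI and bin configuration:

* conventional — mean SUV over the VOI and the tumor-to-muscle ratio
  (TMR), both computed on the raw, undiscretized image;
* histogram — skewness ``m3 / m2^(3/2)`` and non-excess kurtosis
  ``m4 / m2^2`` of the discretized gray-level distribution (population
  moments, divisor N);
* GLCM — entropy ``-sum p log2 p`` and homogeneity
  ``sum p / (1 + |i - j|)`` of the gray-level co-occurrence matrix;
* GLRLM — short- and long-run emphasis ``(1/Nr) sum r(i,j)/j^2`` and
  ``(1/Nr) sum r(i,j) j^2`` of the gray-level run-length matrix.

Texture matrices are built in 3-D over the 13 unique voxel offsets at
Chebyshev distance 1 (neighborhoods in voxel units; no mm correction
for anisotropic spacing).  The GLCM is symmetrized (each pair counted
in both orders) and normalized per direction; runs are maximal
same-level stretches of consecutive in-mask voxels, broken by any
out-of-mask voxel.  Each textural index is computed per direction and
averaged over directions with at least one pair/run; pooling all
directions into a single matrix first is available as a config switch,
as is the entropy log base and computing histogram moments on raw SUV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .quantization import DiscretizationConfig, GrayLevelVolume, discretize
from .volumes import EmptyRegionError, RegionMask, SUVVolume, mask_statistics

__all__ = [
    "FEATURE_NAMES",
    "DIRECTIONS_3D",
    "FeatureConfig",
    "FeatureVector",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "TextureUndefinedError",
    "DegenerateDistributionError",
    "UndefinedRatioError",
    "suv_mean",
    "tmr",
    "histogram_skewness",
    "histogram_kurtosis",
    "glcm",
    "glcm_entropy",
    "glcm_homogeneity",
    "glrlm",
    "glrlm_sre",
    "glrlm_lre",
    "extract_features",
]

#: Output column order: conventional, histogram, GLCM, GLRLM.
FEATURE_NAMES = (
    "suv_mean",
    "tmr",
    "skewness",
    "kurtosis",
    "entropy",
    "homogeneity",
    "sre",
    "lre",
)

#: The 13 unique 3-D offsets at Chebyshev distance 1 (one per +/- pair).
DIRECTIONS_3D: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0)
)
assert len(DIRECTIONS_3D) == 13


class TextureUndefinedError(ValueError):
    """Raised when no voxel pair exists in any direction."""


class DegenerateDistributionError(ValueError):
    """Raised when a histogram moment needs variance > 0 but has none."""


class UndefinedRatioError(ValueError):
    """Raised when the TMR denominator (muscle mean) is not positive."""


@dataclass(frozen=True)
class FeatureConfig:
    """Convention switches for the textural and histogram features."""

    aggregation: str = "average"  # "average" per direction | "pooled" counts
    entropy_base: float = 2.0     # 2 (bits) | 10 | e
    histogram_on_levels: bool = True  # False: moments of raw SUV

    def __post_init__(self) -> None:
        if self.aggregation not in ("average", "pooled"):
            raise ValueError("aggregation must be 'average' or 'pooled'")
        if self.entropy_base <= 1:
            raise ValueError("entropy base must exceed 1")


@dataclass(frozen=True)
class FeatureVector:
    """The 8 named radiomic features for one (VOI, bin configuration).

    ``degenerate_histogram`` is metadata, not a feature: it flags a VOI
    with fewer than 2 distinct gray levels, for which skewness and
    kurtosis are undefined and reported as NaN.
    """

    suv_mean: float
    tmr: float
    skewness: float
    kurtosis: float
    entropy: float
    homogeneity: float
    sre: float
    lre: float
    degenerate_histogram: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Per-direction symmetric co-occurrence counts, shape (13, bins, bins)."""

    counts: np.ndarray
    directions: Tuple[Tuple[int, int, int], ...] = DIRECTIONS_3D

    @property
    def pair_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def probabilities(self) -> np.ndarray:
        """Per-direction probabilities; all-zero where a direction has no pair."""
        totals = self.pair_totals
        out = np.zeros_like(self.counts, dtype=float)
        nonzero = totals > 0
        out[nonzero] = self.counts[nonzero] / totals[nonzero, None, None]
        return out

    def pooled_probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise TextureUndefinedError("no voxel pair in any direction")
        return self.counts.sum(axis=0) / total


@dataclass(frozen=True)
class RunLengthMatrix:
    """Per-direction run counts r(i, j), shape (13, bins, max_run_length).

    Axis 1 indexes gray level i (1-based level i stored at i - 1); axis 2
    indexes run length j (length j stored at j - 1).
    """

    counts: np.ndarray
    directions: Tuple[Tuple[int, int, int], ...] = DIRECTIONS_3D

    @property
    def n_runs(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    @property
    def run_lengths(self) -> np.ndarray:
        """Run lengths j matching axis 2."""
        return np.arange(1, self.counts.shape[2] + 1)


def suv_mean(volume: SUVVolume, voi: RegionMask) -> float:
    """Arithmetic mean of raw SUV over the VOI."""
    return mask_statistics(volume, voi).mean


def tmr(volume: SUVVolume, voi: RegionMask, muscle: RegionMask) -> float:
    """Tumor-to-muscle ratio: VOI mean SUV over reference-muscle mean SUV."""
    muscle_mean = mask_statistics(volume, muscle).mean
    if muscle_mean <= 0:
        raise UndefinedRatioError(f"muscle mean SUV is {muscle_mean}, must be > 0")
    return suv_mean(volume, voi) / muscle_mean


def _moment_input(gray: GrayLevelVolume) -> np.ndarray:
    values = gray.masked_levels.astype(float)
    if values.size == 0:
        raise EmptyRegionError("VOI is empty")
    if np.ptp(values) == 0:
        raise DegenerateDistributionError(
            "histogram moments need >= 2 distinct gray levels"
        )
    return values


def histogram_skewness(gray: GrayLevelVolume) -> float:
    """Population skewness m3 / m2^(3/2) of the in-mask gray levels."""
    return float(stats.skew(_moment_input(gray), bias=True))


def histogram_kurtosis(gray: GrayLevelVolume) -> float:
    """Population non-excess kurtosis m4 / m2^2 (Gaussian -> 3)."""
    return float(stats.kurtosis(_moment_input(gray), fisher=False, bias=True))


def _shift_slices(shape: Sequence[int], offset: Sequence[int]):
    """Slice pairs (at, neighbor) so neighbor = at + offset stays in grid."""
    at, nb = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            at.append(slice(0, n - o))
            nb.append(slice(o, n))
        else:
            at.append(slice(-o, n))
            nb.append(slice(0, n + o))
    return tuple(at), tuple(nb)


def glcm(gray: GrayLevelVolume) -> CooccurrenceMatrix:
    """Symmetric co-occurrence counts over the 13 unit-offset directions."""
    bins = gray.config.bins
    levels, in_mask = gray.levels, gray.mask.flags
    counts = np.zeros((len(DIRECTIONS_3D), bins, bins), dtype=np.int64)
    for d, offset in enumerate(DIRECTIONS_3D):
        at, nb = _shift_slices(levels.shape, offset)
        valid = in_mask[at] & in_mask[nb]
        a = levels[at][valid] - 1
        b = levels[nb][valid] - 1
        if a.size == 0:
            continue
        flat = np.bincount(a * bins + b, minlength=bins * bins).reshape(bins, bins)
        counts[d] = flat + flat.T  # pair counted in both orders
    if counts.sum() == 0:
        raise TextureUndefinedError("no in-mask voxel pair in any direction")
    return CooccurrenceMatrix(counts=counts)


def _directional_mean(per_direction: np.ndarray, has_data: np.ndarray) -> float:
    return float(per_direction[has_data].mean())


def glcm_entropy(matrix: CooccurrenceMatrix, config: FeatureConfig = FeatureConfig()) -> float:
    """Co-occurrence entropy; bits by default."""
    log_base = math.log(config.entropy_base)

    def _entropy(p: np.ndarray) -> float:
        nz = p[p > 0]
        return float(-(nz * (np.log(nz) / log_base)).sum())

    if config.aggregation == "pooled":
        return _entropy(matrix.pooled_probabilities())
    probs = matrix.probabilities()
    has_data = matrix.pair_totals > 0
    per_direction = np.array([_entropy(probs[d]) for d in range(probs.shape[0])])
    return _directional_mean(per_direction, has_data)


def glcm_homogeneity(matrix: CooccurrenceMatrix, config: FeatureConfig = FeatureConfig()) -> float:
    """Inverse-difference homogeneity sum p(i,j) / (1 + |i - j|), in (0, 1]."""
    bins = matrix.counts.shape[1]
    i, j = np.meshgrid(np.arange(bins), np.arange(bins), indexing="ij")
    weight = 1.0 / (1.0 + np.abs(i - j))
    if config.aggregation == "pooled":
        return float((matrix.pooled_probabilities() * weight).sum())
    probs = matrix.probabilities()
    has_data = matrix.pair_totals > 0
    per_direction = (probs * weight).sum(axis=(1, 2))
    return _directional_mean(per_direction, has_data)


def _runs_along(levels: np.ndarray, in_mask: np.ndarray, offset: Tuple[int, int, int]):
    """Yield (level, length) for maximal in-mask runs along one direction."""
    shape = levels.shape
    # same_as_prev[p]: p and p - offset both in-mask with equal level
    same = np.zeros(shape, dtype=bool)
    at, nb = _shift_slices(shape, offset)
    # nb = at + offset, so same holds at the *neighbor* position
    same[nb] = in_mask[at] & in_mask[nb] & (levels[at] == levels[nb])
    starts = in_mask & ~same
    for x, y, z in np.argwhere(starts):
        length = 1
        px, py, pz = x + offset[0], y + offset[1], z + offset[2]
        while (
            0 <= px < shape[0]
            and 0 <= py < shape[1]
            and 0 <= pz < shape[2]
            and same[px, py, pz]
        ):
            length += 1
            px, py, pz = px + offset[0], py + offset[1], pz + offset[2]
        yield int(levels[x, y, z]), length


def glrlm(gray: GrayLevelVolume) -> RunLengthMatrix:
    """Run-length counts over the 13 directions.

    Every in-mask voxel belongs to exactly one run per direction, so
    ``sum_j j * r(i, j)`` equals the VOI voxel count in each direction.
    """
    if gray.mask.count == 0:
        raise EmptyRegionError("VOI is empty")
    bins = gray.config.bins
    levels, in_mask = gray.levels, gray.mask.flags
    per_direction: List[Dict[Tuple[int, int], int]] = []
    max_len = 1
    for offset in DIRECTIONS_3D:
        tally: Dict[Tuple[int, int], int] = {}
        for level, length in _runs_along(levels, in_mask, offset):
            tally[(level, length)] = tally.get((level, length), 0) + 1
            max_len = max(max_len, length)
        per_direction.append(tally)
    counts = np.zeros((len(DIRECTIONS_3D), bins, max_len), dtype=np.int64)
    for d, tally in enumerate(per_direction):
        for (level, length), c in tally.items():
            counts[d, level - 1, length - 1] = c
    return RunLengthMatrix(counts=counts)


def _run_emphasis(matrix: RunLengthMatrix, weight: np.ndarray, aggregation: str) -> float:
    per_dir_sum = (matrix.counts * weight[None, None, :]).sum(axis=(1, 2))
    n_runs = matrix.n_runs
    if aggregation == "pooled":
        total = n_runs.sum()
        if total == 0:
            raise TextureUndefinedError("no run in any direction")
        return float(per_dir_sum.sum() / total)
    has_data = n_runs > 0
    if not has_data.any():
        raise TextureUndefinedError("no run in any direction")
    return float((per_dir_sum[has_data] / n_runs[has_data]).mean())


def glrlm_sre(matrix: RunLengthMatrix, config: FeatureConfig = FeatureConfig()) -> float:
    """Short-run emphasis (1/Nr) sum r(i,j) / j^2, in (0, 1]."""
    j = matrix.run_lengths.astype(float)
    return _run_emphasis(matrix, 1.0 / j**2, config.aggregation)


def glrlm_lre(matrix: RunLengthMatrix, config: FeatureConfig = FeatureConfig()) -> float:
    """Long-run emphasis (1/Nr) sum r(i,j) * j^2, >= 1."""
    j = matrix.run_lengths.astype(float)
    return _run_emphasis(matrix, j**2, config.aggregation)


def extract_features(
    volume: SUVVolume,
    voi: RegionMask,
    muscle: RegionMask,
    config: DiscretizationConfig = DiscretizationConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Measure all 8 features for one VOI under one bin configuration.

    Conventional features use raw SUV; histogram and textural features
    use the discretized gray levels.  A VOI with a single gray level is
    legal for texture (entropy 0, homogeneity 1) but leaves the
    histogram shape undefined; such a VOI is flagged and its skewness
    and kurtosis are NaN rather than an error, so cohort extraction can
    continue.
    """
    gray = discretize(volume, voi, config)
    try:
        skewness = histogram_skewness(gray)
        kurtosis = histogram_kurtosis(gray)
        degenerate = False
    except DegenerateDistributionError:
        if feature_config.histogram_on_levels:
            skewness = kurtosis = float("nan")
            degenerate = True
        else:
            raise
    if not feature_config.histogram_on_levels:
        raw = volume.values[voi.flags]
        if np.ptp(raw) == 0:
            raise DegenerateDistributionError("raw SUV is constant over the VOI")
        skewness = float(stats.skew(raw, bias=True))
        kurtosis = float(stats.kurtosis(raw, fisher=False, bias=True))
        degenerate = False
    cooc = glcm(gray)
    runs = glrlm(gray)
    return FeatureVector(
        suv_mean=suv_mean(volume, voi),
        tmr=tmr(volume, voi, muscle),
        skewness=skewness,
        kurtosis=kurtosis,
        entropy=glcm_entropy(cooc, feature_config),
        homogeneity=glcm_homogeneity(cooc, feature_config),
        sre=glrlm_sre(runs, feature_config),
        lre=glrlm_lre(runs, feature_config),
        degenerate_histogram=degenerate,
    )
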