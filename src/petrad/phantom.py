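"""Synthetic paired-scanner phantom generator.

Emulates the structure of a paired three-condition FDG-PET study of the
same tumor: an early whole-body scan on one scanner and two delayed
regional reconstructions (short and long acquisition) on a second
scanner with a different voxel grid and a different attenuation
correction.  Each subject is a spherical tumor with a smooth
heterogeneity texture, embedded in a low-uptake background with a
separate muscle reference region; each condition applies, in a fixed
order, a delayed-uptake multiplier on the tumor, a scalar
attenuation-correction bias on everything, additive Gaussian noise
whose magnitude reflects acquisition duration, 4-mm Gaussian
post-smoothing, and trilinear resampling onto the condition's voxel
grid.

The generator is a statistical stand-in, not a physics simulation:
there are no sinograms, no reconstruction and no scatter model.  Its
job is to give every downstream stage (segmentation, discretization,
texture features, repeated-measures comparison) inputs with the paired
covariance structure the study design assumes, deterministically from a
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import RegionMask, SUVVolume

__all__ = [
    "PhantomSpec",
    "ConditionSpec",
    "SubjectVariability",
    "CohortRecord",
    "GeometryError",
    "generate_phantom",
    "apply_condition",
    "apply_condition_detailed",
    "generate_cohort",
    "sphere_mask",
    "box_mask",
    "default_phantom_spec",
    "study_conditions",
    "noise_sd_for_duration",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GeometryError(ValueError):
    """Raised when a phantom geometry does not fit its grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and uptake of one synthetic subject.

    ``tumor_heterogeneity`` is the standard deviation (in SUV) of the
    smooth texture field multiplied into the tumor;
    ``texture_correlation_mm`` is the Gaussian correlation length of
    that field.  The muscle region is an axis-aligned box in voxel
    coordinates, ``(lo, hi)`` exclusive at ``hi``, and must be disjoint
    from the tumor sphere.
    """

    shape: Tuple[int, int, int] = (40, 40, 40)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 2.0)
    tumor_center: Tuple[int, int, int] = (20, 20, 20)
    tumor_radius_mm: float = 15.0
    tumor_mean_suv: float = 9.1
    tumor_heterogeneity: float = 1.8
    texture_correlation_mm: float = 6.0
    background_suv: float = 1.0
    muscle_suv: float = 0.7
    muscle_box: Tuple[Tuple[int, int, int], Tuple[int, int, int]] = ((3, 3, 8), (9, 9, 32))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tumor_mean_suv > self.background_suv >= 0:
            raise ValueError("need tumor mean uptake > background uptake >= 0")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be > 0")
        if self.tumor_heterogeneity < 0:
            raise ValueError("heterogeneity amplitude must be >= 0")

    @property
    def tumor_center_mm(self) -> Tuple[float, float, float]:
        return tuple(c * s for c, s in zip(self.tumor_center, self.spacing))

    @property
    def muscle_box_mm(self) -> Tuple[Tuple[float, float, float], Tuple[float, float, float]]:
        lo, hi = self.muscle_box
        return (
            tuple(v * s for v, s in zip(lo, self.spacing)),
            tuple(v * s for v, s in zip(hi, self.spacing)),
        )


@dataclass(frozen=True)
class ConditionSpec:
    """One imaging condition (scanner + protocol) applied to a phantom.

    ``uptake_scale`` multiplies tumor uptake only (delayed-scan biology);
    ``ac_bias`` multiplies everything (attenuation-correction accuracy,
    <= 1 for an underestimating MR-based correction); ``noise_sd`` is the
    additive Gaussian noise level in SUV; ``smoothing_fwhm_mm`` is the
    reconstruction post-filter; ``spacing`` is the condition's voxel grid.
    """

    name: str
    uptake_scale: float = 1.0
    ac_bias: float = 1.0
    noise_sd: float = 0.0
    smoothing_fwhm_mm: float = 4.0
    spacing: Tuple[float, float, float] = (4.0, 4.0, 2.0)

    def __post_init__(self) -> None:
        if self.uptake_scale <= 0:
            raise ValueError("uptake scale must be > 0")
        if not 0 < self.ac_bias <= 1:
            raise ValueError("ac bias must be in (0, 1]")
        if self.noise_sd < 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("noise sd and smoothing fwhm must be >= 0")


@dataclass(frozen=True)
class SubjectVariability:
    """Log-scale standard deviations of per-subject random effects.

    Each subject draws one multiplier ``exp(sd * z)`` per effect, shared
    across all of that subject's conditions, which is what induces the
    cross-condition correlation of the paired design.  All zero means
    every subject is the base phantom.
    """

    radius_sd: float = 0.12
    uptake_sd: float = 0.30
    heterogeneity_sd: float = 0.25


@dataclass(frozen=True)
class CohortRecord:
    """One (subject, condition) image with its ground truth."""

    subject: int
    condition: str
    volume: SUVVolume
    tumor_mask: RegionMask
    muscle_mask: RegionMask
    n_clipped: int = 0


def sphere_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    center_mm: Sequence[float],
    radius_mm: float,
) -> RegionMask:
    """Voxels whose centers lie within ``radius_mm`` of ``center_mm``."""
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return RegionMask(dist2 <= radius_mm**2)


def box_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    lo_mm: Sequence[float],
    hi_mm: Sequence[float],
) -> RegionMask:
    """Voxels whose centers lie in the half-open box [lo_mm, hi_mm)."""
    flags = np.ones(tuple(shape), dtype=bool)
    for axis, (n, s, lo, hi) in enumerate(zip(shape, spacing, lo_mm, hi_mm)):
        centers = np.arange(n) * s
        along = (centers >= lo) & (centers < hi)
        shape_1d = [1, 1, 1]
        shape_1d[axis] = n
        flags &= along.reshape(shape_1d)
    return RegionMask(flags)


def _heterogeneity_field(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    correlation_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth zero-mean random field, later normalized over the tumor."""
    white = rng.standard_normal(shape)
    sigma_vox = [correlation_mm / s for s in spacing]
    return ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")


def generate_phantom(spec: PhantomSpec) -> Tuple[SUVVolume, RegionMask, RegionMask]:
    """Build one noise-free subject image with its ground-truth masks.

    Tumor voxels have mean exactly ``tumor_mean_suv`` and standard
    deviation exactly ``tumor_heterogeneity`` (zero amplitude gives a
    perfectly uniform sphere); background and muscle are constant.
    Deterministic given ``spec.seed``.
    """
    center_mm = spec.tumor_center_mm
    extent_mm = tuple((n - 1) * s for n, s in zip(spec.shape, spec.spacing))
    for c, e in zip(center_mm, extent_mm):
        if c - spec.tumor_radius_mm < 0 or c + spec.tumor_radius_mm > e:
            raise GeometryError(
                f"tumor sphere (center {center_mm} mm, radius {spec.tumor_radius_mm} mm) "
                f"exceeds grid extent {extent_mm} mm"
            )

    tumor = sphere_mask(spec.shape, spec.spacing, center_mm, spec.tumor_radius_mm)
    lo_mm, hi_mm = spec.muscle_box_mm
    muscle = box_mask(spec.shape, spec.spacing, lo_mm, hi_mm)
    if (tumor & muscle).count:
        raise GeometryError("muscle region overlaps the tumor sphere")

    values = np.full(spec.shape, spec.background_suv, dtype=float)
    values[muscle.flags] = spec.muscle_suv

    tumor_values = np.full(tumor.count, spec.tumor_mean_suv)
    if spec.tumor_heterogeneity > 0 and tumor.count > 1:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        texture = _heterogeneity_field(
            spec.shape, spec.spacing, spec.texture_correlation_mm, rng
        )[tumor.flags]
        texture = texture - texture.mean()
        sd = texture.std()
        if sd > 0:
            tumor_values = tumor_values + spec.tumor_heterogeneity * (texture / sd)
    values[tumor.flags] = np.clip(tumor_values, 0.0, None)

    volume = SUVVolume(values=values, spacing=spec.spacing)
    return volume, tumor, muscle


def _resample_trilinear(volume: SUVVolume, new_spacing: Tuple[float, float, float]) -> SUVVolume:
    """Trilinear resampling onto a grid with the same origin and extent."""
    old_shape, old_spacing = volume.shape, volume.spacing
    new_shape = tuple(
        int(math.floor((n - 1) * so / sn)) + 1
        for n, so, sn in zip(old_shape, old_spacing, new_spacing)
    )
    coords = np.meshgrid(
        *(
            np.arange(n) * sn / so
            for n, sn, so in zip(new_shape, new_spacing, old_spacing)
        ),
        indexing="ij",
    )
    values = ndimage.map_coordinates(
        volume.values, np.stack(coords), order=1, mode="nearest"
    )
    return SUVVolume(values=values, spacing=new_spacing, origin=volume.origin)


def apply_condition_detailed(
    volume: SUVVolume,
    tumor_mask: RegionMask,
    cond: ConditionSpec,
    seed: int,
) -> Tuple[SUVVolume, int]:
    """Apply one imaging condition; also return the clipped-voxel count.

    Order of operations is fixed: tumor uptake scaling, attenuation
    bias, additive noise, clipping of negatives to zero (counted),
    Gaussian post-smoothing, resampling to the condition grid.  With
    scale = 1, bias = 1, sd = 0, fwhm = 0 and unchanged spacing the
    output equals the input exactly.
    """
    values = volume.values.copy()
    values[tumor_mask.flags] *= cond.uptake_scale
    values *= cond.ac_bias
    if cond.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        values = values + rng.normal(0.0, cond.noise_sd, size=values.shape)
    negative = values < 0
    n_clipped = int(negative.sum())
    if n_clipped:
        values[negative] = 0.0
    if cond.smoothing_fwhm_mm > 0:
        sigma_vox = [
            cond.smoothing_fwhm_mm * FWHM_TO_SIGMA / s for s in volume.spacing
        ]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="reflect")
    out = SUVVolume(values=values, spacing=volume.spacing, origin=volume.origin)
    if tuple(cond.spacing) != tuple(volume.spacing):
        out = _resample_trilinear(out, tuple(cond.spacing))
    return out, n_clipped


def apply_condition(
    volume: SUVVolume, tumor_mask: RegionMask, cond: ConditionSpec, seed: int
) -> SUVVolume:
    """Like :func:`apply_condition_detailed` but returns the volume only."""
    return apply_condition_detailed(volume, tumor_mask, cond, seed)[0]


def noise_sd_for_duration(reference_sd: float, reference_min: float, duration_min: float) -> float:
    """Count-statistics scaling: noise sd proportional to 1/sqrt(duration)."""
    if duration_min <= 0 or reference_min <= 0:
        raise ValueError("durations must be > 0")
    return reference_sd * math.sqrt(reference_min / duration_min)


def study_conditions(
    delayed_uptake_scale: float = 1.3,
    mr_ac_bias: float = 0.9,
    ct_noise_sd: float = 0.3,
    mr_noise_sd_2min: float = 0.5,
) -> List[ConditionSpec]:
    """The three paired study conditions with this package's defaults.

    Early scan on a 4 x 4 x 2 mm grid with accurate CT-based attenuation
    correction; two delayed reconstructions on a 4 x 4 x 2.78 mm grid
    sharing an MR-based attenuation bias and a tumor-uptake increase,
    differing only in acquisition duration (2 vs 10 min, noise sd scaled
    by 1/sqrt(duration), i.e. a factor sqrt(5)).  All three use a 4-mm
    Gaussian post-filter.
    """
    mr_spacing = (4.0, 4.0, 2.78)
    return [
        ConditionSpec(
            name="early",
            uptake_scale=1.0,
            ac_bias=1.0,
            noise_sd=ct_noise_sd,
            smoothing_fwhm_mm=4.0,
            spacing=(4.0, 4.0, 2.0),
        ),
        ConditionSpec(
            name="delayed-short",
            uptake_scale=delayed_uptake_scale,
            ac_bias=mr_ac_bias,
            noise_sd=mr_noise_sd_2min,
            smoothing_fwhm_mm=4.0,
            spacing=mr_spacing,
        ),
        ConditionSpec(
            name="delayed-long",
            uptake_scale=delayed_uptake_scale,
            ac_bias=mr_ac_bias,
            noise_sd=noise_sd_for_duration(mr_noise_sd_2min, 2.0, 10.0),
            smoothing_fwhm_mm=4.0,
            spacing=mr_spacing,
        ),
    ]


def default_phantom_spec() -> PhantomSpec:
    return PhantomSpec()


def _subject_spec(
    base: PhantomSpec, variability: SubjectVariability, rng: np.random.Generator
) -> PhantomSpec:
    z = rng.standard_normal(3)
    return replace(
        base,
        tumor_radius_mm=base.tumor_radius_mm * math.exp(variability.radius_sd * z[0]),
        tumor_mean_suv=base.background_suv
        + (base.tumor_mean_suv - base.background_suv)
        * math.exp(variability.uptake_sd * z[1]),
        tumor_heterogeneity=base.tumor_heterogeneity
        * math.exp(variability.heterogeneity_sd * z[2]),
    )


def generate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec,
    conditions: Sequence[ConditionSpec],
    variability: SubjectVariability = SubjectVariability(),
    seed: int = 0,
) -> List[CohortRecord]:
    """Paired cohort: per-subject tumors imaged under every condition.

    Subject-level random effects (size, uptake, heterogeneity) are drawn
    once per subject and shared across that subject's conditions, so the
    cross-condition correlation of each feature is induced by
    construction.  Seeds for the subject effects, the texture field and
    the per-condition noise are derived from the master seed by a
    spawn-key scheme ``(subject, condition, stage)``, so adding a
    subject or a condition does not perturb the others' data.
    Ground-truth tumor and muscle masks are rasterized on each
    condition's own grid from the mm-space geometry.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")

    records: List[CohortRecord] = []
    no_variability = (
        variability.radius_sd == variability.uptake_sd
        == variability.heterogeneity_sd == 0.0
    )
    for subject in range(n_subjects):
        effect_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(subject, 0, 0))
        )
        # the texture realization is itself a subject-level random effect:
        # with all variability switched off, subjects are exact replicates
        if no_variability:
            texture_seed = base_spec.seed
        else:
            texture_seed = int(
                np.random.SeedSequence(seed, spawn_key=(subject, 0, 1))
                .generate_state(1)[0] % (2**31)
            )
        spec = replace(
            _subject_spec(base_spec, variability, effect_rng), seed=texture_seed
        )
        base_volume, tumor, muscle = generate_phantom(spec)
        lo_mm, hi_mm = spec.muscle_box_mm
        for cond_idx, cond in enumerate(conditions):
            noise_seed = int(
                np.random.SeedSequence(seed, spawn_key=(subject, cond_idx + 1, 2))
                .generate_state(1)[0] % (2**31)
            )
            imaged, n_clipped = apply_condition_detailed(
                base_volume, tumor, cond, noise_seed
            )
            tumor_gt = sphere_mask(
                imaged.shape, imaged.spacing, spec.tumor_center_mm, spec.tumor_radius_mm
            )
            muscle_gt = box_mask(imaged.shape, imaged.spacing, lo_mm, hi_mm)
            records.append(
                CohortRecord(
                    subject=subject,
                    condition=cond.name,
                    volume=imaged,
                    tumor_mask=tumor_gt,
                    muscle_mask=muscle_gt,
                    n_clipped=n_clipped,
                )
            )
    return records
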