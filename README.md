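# petrad

**A PET radiomic measurement chain with a paired-scanner phantom
simulator, for studying feature stability across scanners and scan
protocols.**

Radiomic features measured from ¹⁸F-FDG PET tumors — mean uptake
(SUVmean), tumor-to-muscle ratio (TMR), histogram shape, and
gray-level-matrix textures — are only useful across institutions if
they survive a change of scanner, attenuation-correction method, scan
delay and acquisition duration. `petrad` implements the full
measurement chain needed to study that question, and a synthetic
paired-phantom cohort generator so the chain can be exercised and
validated end to end without patient data:

1. **Segmentation** — contrast-oriented adaptive threshold: the tumor
   VOI is the connected region above `T = β·I₇₀ + I_bgd` (β = 0.3),
   where I₇₀ is the mean uptake of the supra-70 %-of-maximum core and
   I_bgd the mean of a 2-voxel background shell 6 voxels away,
   capped at 2.5 SUV.
2. **Discretization** — absolute resampling with fixed bounds:
   `R = round[bins·(I − lower)/(upper − lower)]` on [0, 25] SUV at
   8 / 64 / 256 bins (bin widths 3.1 / 0.4 / 0.1 SUV).
3. **Features** — SUVmean, TMR (raw SUV); skewness, non-excess
   kurtosis (histogram); entropy `−Σ p log₂ p` and homogeneity
   `Σ p/(1+|i−j|)` (3-D GLCM, 13 directions); short- and long-run
   emphasis `(1/N_r)Σ r(i,j)/j²`, `(1/N_r)Σ r(i,j)·j²` (3-D GLRLM).
4. **Comparison** — Pearson correlations, percent differences, one-way
   repeated-measures ANOVA with Bonferroni paired post-hocs, and a
   per-feature stability ranking across imaging conditions.

The phantom module simulates the paired design: the same synthetic
tumors imaged under an early scan (4×4×2 mm grid, accurate attenuation
correction) and two delayed reconstructions (4×4×2.78 mm grid, shared
uptake increase and attenuation bias, 2- vs 10-min noise levels), all
with 4-mm Gaussian post-smoothing. See `docs/methods.md` for the model
and every default.

## Worked example

```python
from petrad import phantom, segmentation, features
from petrad.pipeline import search_box_for
from petrad.quantization import DiscretizationConfig

spec = phantom.default_phantom_spec()           # 9.1-SUV tumor, 15-mm radius
volume, tumor, muscle = phantom.generate_phantom(spec)
imaged = phantom.apply_condition(volume, tumor, phantom.study_conditions()[1], seed=42)

gt = phantom.sphere_mask(imaged.shape, imaged.spacing,
                         spec.tumor_center_mm, spec.tumor_radius_mm)
voi = segmentation.segment_tumor(imaged, search_box_for(gt, imaged.spacing))
print(round(segmentation.threshold_value(imaged, search_box_for(gt, imaged.spacing)), 2))
# 4.48      <- T = 0.3 * I70 + Ibgd, in SUV
print(round(segmentation.dice(voi, gt), 2))
# 0.93      <- overlap with the ground-truth sphere

muscle_d = phantom.box_mask(imaged.shape, imaged.spacing, *spec.muscle_box_mm)
vec = features.extract_features(imaged, voi, muscle_d, DiscretizationConfig(bins=64))
print({k: round(v, 2) for k, v in vec.as_dict().items()})
# {'suv_mean': 9.43, 'tmr': 14.43, 'skewness': 0.03, 'kurtosis': 2.73,
#  'entropy': 7.64, 'homogeneity': 0.33, 'sre': 0.95, 'lre': 1.24}
```

The delayed-scan image of a 9.1-SUV phantom tumor segments at threshold
T ≈ 4.5 SUV with Dice 0.93 against truth; at a 0.4-SUV bin width the
VOI has TMR ≈ 14 and near-symmetric, slightly platykurtic histogram
shape — values typical of an FDG-avid pelvic primary tumor.

## The analysis

Numbered drivers under `analysis/` reproduce the full synthetic study
(outputs under `results/`, volumes under `scratch/`):

```sh
python analysis/01_simulate_cohort.py      # 8 subjects x 3 conditions
python analysis/02_extract_features.py     # segment + 8 features x 3 bin counts
python analysis/03_compare_conditions.py   # RM-ANOVA, post-hocs, stability ranking
python analysis/04_bin_width_sensitivity.py  # entropy/homogeneity vs bin count
```

or equivalently `petrad run --seed 0 --out scratch/study` via the CLI
(subcommands `phantom`, `segment`, `features`, `compare` expose the
individual stages).

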