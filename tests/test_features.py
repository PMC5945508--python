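import math

import numpy as np
import pytest

from petrad import phantom
from petrad.features import (
    DIRECTIONS_3D,
    FEATURE_NAMES,
    CooccurrenceMatrix,
    DegenerateDistributionError,
    FeatureConfig,
    RunLengthMatrix,
    TextureUndefinedError,
    UndefinedRatioError,
    extract_features,
    glcm,
    glcm_entropy,
    glcm_homogeneity,
    glrlm,
    glrlm_lre,
    glrlm_sre,
    histogram_kurtosis,
    histogram_skewness,
    suv_mean,
    tmr,
)
from petrad.quantization import DiscretizationConfig
from petrad.segmentation import segment_tumor
from petrad.pipeline import search_box_for
from petrad.volumes import RegionMask, SUVVolume

from .conftest import make_gray, random_gray
from .oracles import (
    brute_glcm,
    brute_glrlm,
    glrlm_dict,
    moment_kurtosis,
    moment_skewness,
)


def strip_1212():
    """1-D strip [1, 2, 1, 2] along x; the only pairs are in the x direction."""
    return make_gray(np.array([1, 2, 1, 2]).reshape(4, 1, 1), bins=2)


class TestConventional:
    def test_mean_and_ratio_hand_values(self):
        values = np.ones((6, 2, 2))
        voi = np.zeros_like(values, bool)
        muscle = np.zeros_like(values, bool)
        voi[:3] = True
        muscle[3:] = True
        values[voi] = 10.0
        values[muscle] = 0.8
        volume = SUVVolume(values, (1, 1, 1))
        assert suv_mean(volume, RegionMask(voi)) == 10.0
        assert tmr(volume, RegionMask(voi), RegionMask(muscle)) == pytest.approx(12.5)

    def test_tmr_of_region_with_itself_is_one(self, rng):
        values = rng.uniform(1, 5, size=(4, 4, 4))
        volume = SUVVolume(values, (1, 1, 1))
        region = RegionMask(rng.random((4, 4, 4)) < 0.5)
        assert tmr(volume, region, region) == pytest.approx(1.0)

    def test_zero_muscle_mean_raises(self):
        volume = SUVVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        mask = RegionMask(np.ones((2, 2, 2), bool))
        with pytest.raises(UndefinedRatioError):
            tmr(volume, mask, mask)


class TestHistogram:
    def test_symmetric_levels_have_zero_skewness(self):
        gray = make_gray(np.array([1, 1, 3, 3]).reshape(4, 1, 1), bins=4)
        assert histogram_skewness(gray) == pytest.approx(0.0)

    def test_positive_skew_matches_moment_oracle(self):
        levels = [1, 1, 1, 5]
        gray = make_gray(np.array(levels).reshape(4, 1, 1), bins=8)
        value = histogram_skewness(gray)
        assert value > 0
        assert value == pytest.approx(moment_skewness(levels))

    def test_translation_invariance(self):
        a = make_gray(np.array([1, 1, 1, 5]).reshape(4, 1, 1), bins=16)
        b = make_gray(np.array([4, 4, 4, 8]).reshape(4, 1, 1), bins=16)
        assert histogram_skewness(a) == pytest.approx(histogram_skewness(b))
        assert histogram_kurtosis(a) == pytest.approx(histogram_kurtosis(b))

    def test_reflection_flips_skew_sign(self):
        a = make_gray(np.array([1, 1, 1, 5]).reshape(4, 1, 1), bins=8)
        reflected = make_gray(np.array([8, 8, 8, 4]).reshape(4, 1, 1), bins=8)
        assert histogram_skewness(reflected) == pytest.approx(-histogram_skewness(a))

    def test_two_point_symmetric_kurtosis_is_minimum(self):
        gray = make_gray(np.array([1, 1, 3, 3]).reshape(4, 1, 1), bins=4)
        assert histogram_kurtosis(gray) == pytest.approx(1.0)

    def test_discrete_uniform_kurtosis_exact(self):
        levels = [1, 2, 3, 4, 5]
        gray = make_gray(np.array(levels).reshape(5, 1, 1), bins=8)
        assert histogram_kurtosis(gray) == pytest.approx(1.7)
        assert histogram_kurtosis(gray) == pytest.approx(moment_kurtosis(levels))

    def test_gaussian_sample_kurtosis_near_three(self, rng):
        sample = np.clip(np.round(rng.normal(128, 20, size=20000)), 1, 256)
        gray = make_gray(sample.reshape(-1, 1, 1).astype(int), bins=256)
        # 3 sigma of the kurtosis estimator ~ sqrt(24 / n)
        assert histogram_kurtosis(gray) == pytest.approx(3.0, abs=3 * math.sqrt(24 / 20000))

    def test_constant_levels_degenerate(self):
        gray = make_gray(np.full((3, 3, 3), 5), bins=8)
        with pytest.raises(DegenerateDistributionError):
            histogram_skewness(gray)


class TestGLCM:
    def test_constant_voi_single_diagonal_entry(self):
        gray = make_gray(np.full((3, 3, 3), 4), bins=8)
        matrix = glcm(gray)
        probs = matrix.probabilities()
        for d in range(13):
            assert probs[d, 3, 3] == pytest.approx(1.0)
            assert probs[d].sum() == pytest.approx(1.0)

    def test_strip_1212_off_diagonal(self):
        matrix = glcm(strip_1212())
        probs = matrix.probabilities()
        x_dir = DIRECTIONS_3D.index((1, 0, 0))
        assert probs[x_dir, 0, 1] == pytest.approx(0.5)
        assert probs[x_dir, 1, 0] == pytest.approx(0.5)
        assert matrix.pair_totals[x_dir] == 6  # 3 adjacent pairs, both orders
        others = [d for d in range(13) if d != x_dir]
        assert matrix.pair_totals[others].sum() == 0

    @pytest.mark.parametrize("bins", [8, 64])
    def test_matches_brute_force_enumeration(self, rng, bins):
        for _ in range(25):
            gray = random_gray(rng, bins)
            try:
                matrix = glcm(gray)
            except TextureUndefinedError:
                continue
            for d, offset in enumerate(DIRECTIONS_3D):
                expected = brute_glcm(gray.levels, gray.mask.flags, bins, offset)
                np.testing.assert_array_equal(matrix.counts[d], expected)

    def test_symmetry(self, rng):
        gray = random_gray(rng, 8)
        try:
            matrix = glcm(gray)
        except TextureUndefinedError:
            pytest.skip("no pairs in sample")
        for d in range(13):
            np.testing.assert_array_equal(matrix.counts[d], matrix.counts[d].T)

    def test_single_voxel_has_no_texture(self):
        gray = make_gray(np.array([[[3]]]), bins=8)
        with pytest.raises(TextureUndefinedError):
            glcm(gray)


class TestGLCMFeatures:
    def test_constant_voi_entropy_zero_homogeneity_one(self):
        matrix = glcm(make_gray(np.full((3, 3, 3), 4), bins=8))
        assert glcm_entropy(matrix) == pytest.approx(0.0)
        assert glcm_homogeneity(matrix) == pytest.approx(1.0)

    def test_strip_entropy_one_bit_homogeneity_half(self):
        matrix = glcm(strip_1212())
        assert glcm_entropy(matrix) == pytest.approx(1.0)  # -2 * 0.5 log2 0.5
        assert glcm_homogeneity(matrix) == pytest.approx(0.5)  # all mass at |i-j| = 1

    def test_uniform_distribution_reaches_log2_k(self):
        counts = np.zeros((13, 4, 4), dtype=np.int64)
        counts[0] = np.ones((4, 4))  # 16 equiprobable cells in one direction
        matrix = CooccurrenceMatrix(counts=counts)
        assert glcm_entropy(matrix) == pytest.approx(math.log2(16))

    def test_entropy_base_switch(self):
        matrix = glcm(strip_1212())
        bits = glcm_entropy(matrix, FeatureConfig(entropy_base=2))
        dits = glcm_entropy(matrix, FeatureConfig(entropy_base=10))
        assert dits == pytest.approx(bits * math.log10(2))

    def test_homogeneity_in_unit_interval(self, rng):
        for _ in range(20):
            gray = random_gray(rng, 8)
            try:
                value = glcm_homogeneity(glcm(gray))
            except TextureUndefinedError:
                continue
            assert 0 < value <= 1


class TestGLRLM:
    def test_single_voxel_one_run_per_direction(self):
        matrix = glrlm(make_gray(np.array([[[3]]]), bins=8))
        assert (matrix.n_runs == 1).all()
        assert glrlm_sre(matrix) == 1.0
        assert glrlm_lre(matrix) == 1.0

    def test_constant_strip_single_run_along_x(self):
        length = 5
        matrix = glrlm(make_gray(np.full((length, 1, 1), 2), bins=4))
        x_dir = DIRECTIONS_3D.index((1, 0, 0))
        assert matrix.counts[x_dir, 1, length - 1] == 1
        assert matrix.n_runs[x_dir] == 1

    def test_single_run_closed_forms(self):
        # craft a matrix with data only in one direction: one run of length L
        length = 4
        counts = np.zeros((13, 2, length), dtype=np.int64)
        counts[0, 0, length - 1] = 1
        matrix = RunLengthMatrix(counts=counts)
        assert glrlm_sre(matrix) == pytest.approx(1 / length**2)
        assert glrlm_lre(matrix) == pytest.approx(length**2)

    @pytest.mark.parametrize("bins", [8, 64])
    def test_matches_brute_force_line_scan(self, rng, bins):
        for _ in range(25):
            gray = random_gray(rng, bins)
            matrix = glrlm(gray)
            for d, offset in enumerate(DIRECTIONS_3D):
                expected = brute_glrlm(gray.levels, gray.mask.flags, bins, offset)
                assert glrlm_dict(matrix.counts, d) == expected

    def test_conservation_every_direction(self, rng):
        """Each voxel lies in exactly one run per direction: sum j r(i,j) = N."""
        for _ in range(10):
            gray = random_gray(rng, 8)
            matrix = glrlm(gray)
            weighted = (matrix.counts * matrix.run_lengths[None, None, :]).sum(axis=(1, 2))
            assert (weighted == gray.mask.count).all()

    def test_sre_lre_bounds_and_cauchy_schwarz(self, rng):
        for _ in range(20):
            gray = random_gray(rng, 8)
            matrix = glrlm(gray)
            j = matrix.run_lengths.astype(float)
            n_runs = matrix.n_runs
            for d in range(13):
                if n_runs[d] == 0:
                    continue
                sre_d = (matrix.counts[d] / j[None, :] ** 2).sum() / n_runs[d]
                lre_d = (matrix.counts[d] * j[None, :] ** 2).sum() / n_runs[d]
                assert 0 < sre_d <= 1
                assert lre_d >= 1
                assert sre_d * lre_d >= 1 - 1e-12


class TestExtractFeatures:
    def test_vector_has_exactly_eight_named_features(self, default_phantom):
        spec, volume, tumor, muscle = default_phantom
        vector = extract_features(volume, tumor, muscle)
        assert len(vector.as_dict()) == 8
        assert tuple(vector.as_dict()) == FEATURE_NAMES

    def test_constant_tumor_flags_degenerate_histogram(self):
        values = np.ones((9, 9, 9))
        voi = np.zeros_like(values, bool)
        voi[3:6, 3:6, 3:6] = True
        muscle = np.zeros_like(values, bool)
        muscle[0:2, 0:2, 0:2] = True
        values[voi] = 10.0
        values[muscle] = 0.8
        vector = extract_features(
            SUVVolume(values, (1, 1, 1)), RegionMask(voi), RegionMask(muscle)
        )
        assert vector.degenerate_histogram
        assert math.isnan(vector.skewness) and math.isnan(vector.kurtosis)
        assert vector.entropy == pytest.approx(0.0)
        assert vector.homogeneity == pytest.approx(1.0)
        assert vector.suv_mean == 10.0

    def test_full_pipeline_deterministic(self, default_phantom):
        spec, volume, tumor, muscle = default_phantom
        cond = phantom.study_conditions()[1]
        imaged = phantom.apply_condition(volume, tumor, cond, seed=13)
        gt = phantom.sphere_mask(imaged.shape, imaged.spacing,
                                 spec.tumor_center_mm, spec.tumor_radius_mm)
        mus = phantom.box_mask(imaged.shape, imaged.spacing, *spec.muscle_box_mm)
        voi = segment_tumor(imaged, search_box_for(gt, imaged.spacing))
        a = extract_features(imaged, voi, mus)
        b = extract_features(imaged, voi, mus)
        assert a == b

    def test_bin_count_trend_entropy_up_homogeneity_down(self, default_phantom):
        """Finer absolute bins raise entropy and lower homogeneity on the
        same heterogeneous VOI."""
        spec, volume, tumor, muscle = default_phantom
        entropies, homogeneities = [], []
        for bins in (8, 64, 256):
            vector = extract_features(
                volume, tumor, muscle, DiscretizationConfig(bins=bins)
            )
            entropies.append(vector.entropy)
            homogeneities.append(vector.homogeneity)
        assert entropies[0] <= entropies[1] <= entropies[2]
        assert homogeneities[0] >= homogeneities[1] >= homogeneities[2]

    def test_aggregation_switch_changes_convention_not_scale(self, default_phantom):
        spec, volume, tumor, muscle = default_phantom
        averaged = extract_features(volume, tumor, muscle)
        pooled = extract_features(
            volume, tumor, muscle, feature_config=FeatureConfig(aggregation="pooled")
        )
        for name in ("entropy", "homogeneity", "sre", "lre"):
            a, p = getattr(averaged, name), getattr(pooled, name)
            assert a == pytest.approx(p, rel=0.2)
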