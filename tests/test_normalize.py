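"""Brain masks, ratio histograms and the three normalization methods."""

import numpy as np
import pytest

from petnorm import (
    BrainMask,
    GlobalMeanNormalizer,
    HistogramNormalizer,
    VoxelImage,
    brain_mask_from_template,
    normalization_factor_global_mean,
    normalization_factor_histogram,
    normalize_none,
    ratio_histogram,
    ratio_image,
    sample_population,
    spherical_lesion_mask,
)
from petnorm.errors import NumericalDomainError, ValidationError


def ratio_volume(values, shape=None):
    """Pack a 1D array of ratios into a cubic ratio image + all-true mask."""
    n = values.size
    side = int(np.ceil(n ** (1 / 3)))
    data = np.full(side**3, np.nan)
    data[:n] = values
    data = data.reshape(side, side, side)
    mask = BrainMask(np.isfinite(data))
    return VoxelImage(data, 1.0, unit="ratio"), mask


class TestBrainMask:
    def test_constant_template_keeps_every_voxel(self):
        # strict inequality edge: every positive constant exceeds half of
        # itself, so the whole grid is brain
        img = VoxelImage(np.full((4, 4, 4), 2.0), 1.0)
        mask = brain_mask_from_template(img)
        assert mask.n_voxels == 64

    def test_binary_template_keeps_only_high_voxels(self):
        data = np.zeros((4, 4, 4))
        data[1:3, 1:3, 1:3] = 1.0
        mask = brain_mask_from_template(VoxelImage(data, 1.0), 0.5)
        assert np.array_equal(mask.mask, data == 1.0)

    def test_all_zero_template_rejected(self):
        with pytest.raises(ValidationError):
            brain_mask_from_template(VoxelImage(np.zeros((3, 3, 3)), 1.0))

    def test_voxel_count_matches_exhaustive_scan(self, small_template):
        mask = brain_mask_from_template(small_template, 0.5)
        threshold = 0.5 * small_template.data.max()
        count = 0
        for v in small_template.data.ravel():
            count += v > threshold
        assert mask.n_voxels == count


class TestRatioImage:
    def test_identical_images_give_unit_ratio(self, small_template):
        mask = brain_mask_from_template(small_template)
        out = ratio_image(small_template, small_template, mask)
        assert np.allclose(out.data[mask.mask], 1.0)
        assert np.all(np.isnan(out.data[~mask.mask]))

    def test_doubled_image_gives_ratio_two(self, small_template):
        mask = brain_mask_from_template(small_template)
        doubled = small_template.with_data(2 * small_template.data)
        out = ratio_image(doubled, small_template, mask)
        assert np.allclose(out.data[mask.mask], 2.0)

    def test_matches_per_voxel_division_oracle(self, small_template, rng):
        mask = brain_mask_from_template(small_template)
        img = small_template.with_data(rng.random(small_template.shape) + 0.5)
        out = ratio_image(img, small_template, mask)
        for idx in map(tuple, np.argwhere(mask.mask)[::97]):
            assert out.data[idx] == img.data[idx] / small_template.data[idx]

    def test_zero_template_voxel_inside_mask_raises(self):
        template = VoxelImage(np.ones((3, 3, 3)), 1.0)
        template.data[1, 1, 1] = 0.0
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(NumericalDomainError, match=r"\(1, 1, 1\)"):
            ratio_image(VoxelImage(np.ones((3, 3, 3)), 1.0), template, mask)


class TestRatioHistogram:
    def test_all_unit_ratios_concentrate_in_one_bin(self):
        img, mask = ratio_volume(np.ones(500))
        hist = ratio_histogram(img, mask)
        in_bin = (hist.bin_edges[:-1] <= 1.0) & (hist.bin_edges[1:] > 1.0)
        assert hist.counts[in_bin].sum() == 500
        assert hist.counts.sum() == 500
        assert abs(hist.raw_mode_bin_center - 1.0) <= 0.01

    def test_gaussian_center_recovers_generating_mean(self, rng):
        values = rng.normal(1.2, 0.05, size=100_000)
        img, mask = ratio_volume(values)
        hist = ratio_histogram(img, mask)
        assert hist.fit_converged
        assert abs(hist.gauss_center - 1.2) < 0.01
        assert abs(hist.gauss_sigma - 0.05) < 0.01

    def test_bimodal_mode_sits_at_major_peak_not_lesion_tail(self, rng):
        # 80% of ratios near one, 20% near 0.6: the lesion-like tail must
        # not capture the mode
        values = np.concatenate(
            [rng.normal(1.0, 0.04, 40_000), rng.normal(0.6, 0.04, 10_000)]
        )
        img, mask = ratio_volume(values)
        hist = ratio_histogram(img, mask)
        assert abs(hist.raw_mode_bin_center - 1.0) < 0.05
        assert abs(hist.peak - 1.0) < 0.05

    def test_counts_conserve_in_mask_voxels(self, rng):
        values = rng.lognormal(0.0, 0.3, size=5000)  # some ratios exceed 3
        img, mask = ratio_volume(values)
        hist = ratio_histogram(img, mask)
        assert hist.counts.sum() == values.size

    def test_too_few_voxels_rejected(self, rng):
        img, mask = ratio_volume(rng.random(50) + 0.5)
        with pytest.raises(ValidationError):
            ratio_histogram(img, mask)


class TestHistogramFactor:
    def test_pure_scaling_recovers_k_within_one_bin(self, small_template):
        for k in (0.5, 1.3, 2.0):
            img = small_template.with_data(k * small_template.data)
            res = normalization_factor_histogram(img, small_template)
            assert abs(res.factor - k) <= 0.01
            assert np.allclose(
                res.normalized_image.data, small_template.data * (k / res.factor)
            )

    def test_template_against_itself_gives_unit_factor(self, small_template):
        res = normalization_factor_histogram(small_template, small_template)
        assert abs(res.factor - 1.0) <= 0.01

    def test_mode_robust_to_hypometabolic_lesion(self, small_template, small_spec):
        # 10% of the mask halved: the mean moves, the mode must not
        mask = brain_mask_from_template(small_template)
        k = 1.4
        data = k * small_template.data.copy()
        in_mask = np.argwhere(mask.mask)
        lesioned = in_mask[: int(0.1 * len(in_mask))]
        data[tuple(lesioned.T)] *= 0.5
        img = small_template.with_data(data)
        res = normalization_factor_histogram(img, small_template, mask)
        assert abs(res.factor - k) <= 0.01

    def test_scale_equivariance(self, small_spec, small_template):
        pop = sample_population(small_template, 2, small_spec, seed=8)
        img = pop[0][0]
        norm = HistogramNormalizer().fit(small_template)
        base = norm.factor(img)
        for k in (0.5, 2.0):
            scaled = img.with_data(k * img.data)
            assert abs(norm.factor(scaled) - k * base) < 0.02 * k * base


class TestGlobalMeanFactor:
    def test_constant_image_normalizes_to_one(self, small_template):
        mask = brain_mask_from_template(small_template)
        img = small_template.with_data(np.full(small_template.shape, 4.2))
        res = normalization_factor_global_mean(img, mask)
        assert res.factor == pytest.approx(4.2)
        assert np.allclose(res.normalized_image.data, 1.0)

    def test_factor_equals_exhaustive_summation(self, small_template, rng):
        mask = brain_mask_from_template(small_template)
        img = small_template.with_data(rng.random(small_template.shape) + 0.1)
        res = normalization_factor_global_mean(img, mask)
        total, count = 0.0, 0
        for idx in map(tuple, np.argwhere(mask.mask)):
            total += img.data[idx]
            count += 1
        assert res.factor == pytest.approx(total / count, rel=1e-12)

    def test_lesion_drags_mean_below_mode(self, small_template, small_spec):
        mask = brain_mask_from_template(small_template)
        lesion = spherical_lesion_mask(small_spec, radius_mm=1.6) & mask.mask
        data = small_template.data.copy()
        data[lesion] *= 0.4
        img = small_template.with_data(data)
        hist_factor = normalization_factor_histogram(img, small_template, mask).factor
        mean_factor = normalization_factor_global_mean(img, mask).factor
        assert mean_factor < hist_factor


class TestNoNormalization:
    def test_passthrough(self, small_template):
        res = normalize_none(small_template)
        assert res.factor == 1.0
        assert res.method == "none"
        assert np.array_equal(res.normalized_image.data, small_template.data)
        assert res.normalized_image.unit == "SUV"


class TestRobustnessDominance:
    def test_histogram_beats_global_mean_under_lesions(self, small_spec, small_template):
        """With focal multiplicative lesions (<20% of mask), the histogram
        factor is at least as close to the true scale as the mean factor in
        nearly all random phantoms."""
        mask = brain_mask_from_template(small_template)
        lesion = spherical_lesion_mask(small_spec, radius_mm=2.0) & mask.mask
        assert 0 < lesion.sum() <= 0.2 * mask.n_voxels
        hist = HistogramNormalizer().fit(small_template)
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            pop = sample_population(
                small_template, 2, small_spec, seed=seed,
                lesion_mask=lesion, lesion_factor=0.5,
            )
            img, truth = pop[0]
            h_err = abs(hist.factor(img) - truth.global_scale)
            g_err = abs(
                normalization_factor_global_mean(img, mask).factor
                - truth.global_scale
            )
            wins += h_err <= g_err
        assert wins >= 0.95 * n_rep
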