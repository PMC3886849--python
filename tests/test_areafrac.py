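"""Unit and property tests for the histogram-reflection area-fraction estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliaquant import areafrac
from gliaquant.areafrac import (
    EmptyROIError,
    IntensityHistogram,
    animal_area_fraction,
    compute_histogram,
    estimate_background_area,
    labeled_area_fraction,
    locate_background_peak,
)
from gliaquant.synth_images import ImageSpec, IntensityImage, generate_section_image

from conftest import make_image_from_values


def hist_from_counts(counts: dict[int, int], n_levels: int = 256) -> IntensityHistogram:
    arr = np.zeros(n_levels, dtype=int)
    for level, c in counts.items():
        arr[level] = c
    return IntensityHistogram(bin_values=np.arange(n_levels), counts=arr,
                              total=int(arr.sum()))


class TestComputeHistogram:
    def test_enumerates_roi_pixels(self):
        img = IntensityImage(
            pixels=np.array([[10, 10], [10, 200]], dtype=np.uint8),
            roi_mask=np.ones((2, 2), dtype=bool))
        h = compute_histogram(img)
        assert h.counts[10] == 3 and h.counts[200] == 1 and h.total == 4

    def test_roi_mask_excludes_pixels(self):
        roi = np.array([[True, True], [True, False]])
        img = IntensityImage(
            pixels=np.array([[10, 10], [10, 200]], dtype=np.uint8), roi_mask=roi)
        h = compute_histogram(img)
        assert h.counts[10] == 3 and h.counts[200] == 0 and h.total == 3

    def test_uniform_image_single_bin(self):
        img = make_image_from_values([42] * 50)
        h = compute_histogram(img)
        assert h.counts[42] == 50 and h.counts.sum() == 50

    def test_empty_roi_raises(self):
        img = IntensityImage(pixels=np.zeros((4, 4), dtype=np.uint8),
                             roi_mask=np.zeros((4, 4), dtype=bool))
        with pytest.raises(EmptyROIError):
            compute_histogram(img)


class TestBackgroundPeak:
    def test_centroid_of_three_highest_bins(self):
        h = hist_from_counts({0: 1, 1: 3, 2: 5, 3: 3, 4: 1})
        peak, degenerate = locate_background_peak(h)
        assert peak == pytest.approx(2.0) and not degenerate

    def test_ties_prefer_lower_intensity(self):
        # two symmetric modes with equal triplet mass: the darker one wins
        h = hist_from_counts({1: 5, 2: 5, 10: 5, 11: 5})
        peak, _ = locate_background_peak(h)
        assert peak == pytest.approx(1.5)

    def test_peak_is_densest_adjacent_triplet(self):
        # window 5..7 carries 17 pixels, more than any other triplet
        h = hist_from_counts({5: 3, 6: 7, 7: 7, 9: 3})
        peak, _ = locate_background_peak(h)
        assert peak == pytest.approx((5 * 3 + 6 * 7 + 7 * 7) / 17)

    def test_isolated_bright_bin_does_not_capture_peak(self):
        # the stained-pixel bin outnumbers the modal background bin but has
        # no dense neighborhood, so the background mode keeps the peak
        h = hist_from_counts({0: 1, 1: 3, 2: 5, 3: 3, 4: 1, 200: 10})
        peak, _ = locate_background_peak(h)
        assert peak == pytest.approx(2.0)

    def test_single_bin_degenerate(self):
        h = hist_from_counts({30: 12})
        peak, degenerate = locate_background_peak(h)
        assert peak == 30 and degenerate

    def test_gaussian_background_peak_near_mode(self):
        # symmetric background at 50: located peak within one intensity level
        hits = []
        for seed in range(100):
            img = generate_section_image(ImageSpec(
                width=64, height=64, true_fraction=0.0, bg_mean=50.0,
                bg_sd=4.0, seed=seed))
            peak, _ = locate_background_peak(compute_histogram(img))
            hits.append(abs(peak - 50.0) <= 1.0)
        assert np.mean(hits) > 0.95


class TestBackgroundArea:
    def test_symmetric_background_consumes_total(self):
        h = hist_from_counts({0: 1, 1: 3, 2: 5, 3: 3, 4: 1})
        bg = estimate_background_area(h, 2.0)
        assert bg.background_count == 13 == h.total and not bg.clamp_applied

    def test_signal_bin_left_out(self):
        h = hist_from_counts({0: 1, 1: 3, 2: 5, 3: 3, 4: 1, 200: 10})
        bg = estimate_background_area(h, 2.0)
        assert bg.background_count == 13 and h.total == 23

    def test_single_bin_no_clamp(self):
        h = hist_from_counts({7: 40})
        bg = estimate_background_area(h, 7.0)
        assert bg.background_count == 40 and not bg.clamp_applied

    def test_clamped_when_peak_above_median(self):
        # heavy mass below the peak bin: doubling overshoots and clamps
        h = hist_from_counts({0: 50, 10: 5, 11: 4, 12: 6})
        bg = estimate_background_area(h, 11.0)
        assert bg.background_count == h.total and bg.clamp_applied

    @pytest.mark.parametrize("peak,expected_below", [(2.0, 4), (2.49, 4), (2.5, 4), (2.51, 9)])
    def test_fractional_peak_rounds_half_toward_background(self, peak, expected_below):
        h = hist_from_counts({0: 1, 1: 3, 2: 5, 3: 3, 4: 1})
        bg = estimate_background_area(h, peak)
        raw = 2 * expected_below + h.counts[int(np.ceil(peak - 0.5))]
        assert bg.background_count == min(raw, h.total)


class TestLabeledAreaFraction:
    def test_worked_bimodal_fraction(self, worked_bimodal_image):
        assert labeled_area_fraction(worked_bimodal_image) == pytest.approx(10 / 23)

    def test_background_only_is_zero(self, background_only_image):
        assert labeled_area_fraction(background_only_image) == 0.0

    def test_pure_background_synthetic_small(self):
        fracs = [
            labeled_area_fraction(generate_section_image(
                ImageSpec(width=96, height=96, true_fraction=0.0, seed=s)))
            for s in range(50)
        ]
        assert np.mean(np.abs(fracs)) <= 0.02

    def test_recovery_at_moderate_fraction(self):
        errs = [
            labeled_area_fraction(generate_section_image(
                ImageSpec(width=96, height=96, true_fraction=0.40, seed=s))) - 0.40
            for s in range(30)
        ]
        assert np.abs(np.mean(errs)) < 0.01 and np.max(np.abs(errs)) < 0.03

    def test_degenerate_histogram_warns_and_returns_zero(self):
        img = make_image_from_values([9] * 10 + [200] * 5)  # two nonzero bins
        with pytest.warns(UserWarning, match="degenerate"):
            assert labeled_area_fraction(img) == 0.0

    def test_matches_threshold_oracle_on_separated_images(self):
        # independent oracle: count pixels above the midpoint between modes
        for seed in range(10):
            spec = ImageSpec(width=96, height=96, true_fraction=0.3, seed=seed)
            img = generate_section_image(spec)
            cut = (spec.bg_mean + spec.signal_mean) / 2
            oracle = np.mean(img.pixels[img.roi_mask] > cut)
            assert labeled_area_fraction(img) == pytest.approx(oracle, abs=0.03)

    def test_monotone_in_signal_replacement(self):
        # converting background pixels to signal never decreases the estimate
        rng = np.random.default_rng(3)
        img = generate_section_image(ImageSpec(width=96, height=96,
                                               true_fraction=0.0, seed=5))
        pixels = img.pixels.copy()
        order = rng.permutation(pixels.size)
        prev = labeled_area_fraction(img)
        n = pixels.size
        for frac in [0.1, 0.2, 0.4, 0.6, 0.8]:
            idx = order[: int(frac * n)]
            flat = pixels.ravel()
            flat[idx] = np.clip(rng.normal(160, 30, idx.size), 0, 255).astype(np.uint8)
            cur = labeled_area_fraction(IntensityImage(
                pixels=pixels, roi_mask=img.roi_mask, bit_depth=8))
            assert cur >= prev
            prev = cur

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fraction_bounded_for_arbitrary_images(self, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        img = IntensityImage(pixels=pixels,
                             roi_mask=np.ones((16, 16), dtype=bool), bit_depth=8)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = labeled_area_fraction(img)
        assert 0.0 <= f <= 1.0

    def test_all_signal_extreme_bounded(self):
        img = make_image_from_values([200] * 30 + [201] * 40 + [202] * 30)
        assert 0.0 <= labeled_area_fraction(img) <= 1.0


class TestAnimalAveraging:
    def test_triplicate_mean(self):
        res = animal_area_fraction([0.30, 0.35, 0.40], "GFAP")
        assert res.animal_fraction == pytest.approx(0.35)

    def test_single_section(self):
        assert animal_area_fraction([0.5], "Iba1").animal_fraction == 0.5

    def test_permutation_invariant(self):
        a = animal_area_fraction([0.1, 0.5, 0.3], "GFAP").animal_fraction
        b = animal_area_fraction([0.5, 0.3, 0.1], "GFAP").animal_fraction
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            animal_area_fraction([], "GFAP")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            animal_area_fraction([0.2, 1.4], "GFAP")
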