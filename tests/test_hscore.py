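"""Superpixel segmentation, intensity classification and H-scoring."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dabquant import (
    ClassCounts,
    IntensityThresholds,
    ODChannel,
    SlicParams,
    classify_superpixels,
    hscore,
    hscore_roi,
    intensity_distribution,
    slic_segment,
    thresholds_from_quantiles,
)
from dabquant.synthetic import GENERATION_THRESHOLDS, render_scene, scene_for_metric
from dabquant import StainVectors, deconvolve_dab, rgb_to_od

THRESH = IntensityThresholds(0.2, 0.4, 0.8)


def brute_force_hscore(values, labels, thresholds):
    """Independent oracle: per-label mean by direct averaging, explicit bins."""
    n = labels.max()
    w = m = h = 0
    for k in range(1, n + 1):
        vals = [values[i, j] for i, j in zip(*np.nonzero(labels == k))]
        mean = sum(vals) / len(vals)
        if mean < thresholds.t_weak:
            pass
        elif mean < thresholds.t_moderate:
            w += 1
        elif mean < thresholds.t_strong:
            m += 1
        else:
            h += 1
    return (w * 100 + m * 200 + h * 300) / n


class TestSlic:
    def test_uniform_roi_superpixel_count(self):
        """100×100 px at 1 µm/px, 10 µm diameter → ~10×10 seeds → 100 ± 20%."""
        ch = ODChannel(np.full((100, 100), 0.3), 1.0)
        spmap = slic_segment(ch, np.ones((100, 100), bool), SlicParams(target_diameter=10))
        assert 80 <= spmap.n_superpixels <= 120

    def test_single_pixel_roi(self):
        ch = ODChannel(np.full((20, 20), 0.5), 1.0)
        roi = np.zeros((20, 20), bool)
        roi[10, 10] = True
        with pytest.warns(UserWarning):
            spmap = slic_segment(ch, roi, SlicParams(target_diameter=10))
        assert spmap.n_superpixels == 1
        assert spmap.labels[10, 10] == 1
        assert spmap.area_px.sum() == 1

    def test_partition_invariant(self, rng):
        """Every ROI pixel has exactly one label ≥ 1; none outside; areas sum."""
        ch = ODChannel(rng.uniform(0, 1, (64, 64)), 1.0)
        roi = np.zeros((64, 64), bool)
        roi[8:60, 4:50] = True
        spmap = slic_segment(ch, roi, SlicParams(target_diameter=8))
        assert np.all(spmap.labels[roi] >= 1)
        assert np.all(spmap.labels[~roi] == 0)
        assert spmap.area_px.sum() == roi.sum()
        # labels are 1..n with no gaps
        assert set(np.unique(spmap.labels[roi])) == set(range(1, spmap.n_superpixels + 1))

    def test_boundary_adherence_on_half_planes(self):
        """Low compactness: superpixels do not straddle a sharp OD boundary."""
        od = np.zeros((60, 60))
        od[:, 30:] = 1.0
        ch = ODChannel(od, 1.0)
        spmap = slic_segment(
            ch, np.ones((60, 60), bool), SlicParams(target_diameter=10, compactness=0.01)
        )
        cols = np.arange(60)[None, :]
        for k in range(1, spmap.n_superpixels + 1):
            mask = spmap.labels == k
            left = int((mask & (cols < 30)).sum())
            assert min(left, int(mask.sum()) - left) <= 1

    def test_connected_labels(self, rng):
        ch = ODChannel(rng.uniform(0, 1, (50, 50)), 1.0)
        spmap = slic_segment(ch, np.ones((50, 50), bool), SlicParams(target_diameter=10))
        from skimage.measure import label as cc

        for k in range(1, spmap.n_superpixels + 1):
            assert cc(spmap.labels == k, connectivity=1).max() == 1

    def test_empty_roi_rejected(self):
        ch = ODChannel(np.zeros((10, 10)), 1.0)
        with pytest.raises(ValueError):
            slic_segment(ch, np.zeros((10, 10), bool))


class TestClassification:
    def test_all_below_weak(self):
        spmap_means = np.full(12, 0.05)
        counts = _counts_from_means(spmap_means)
        assert (counts.SP_W, counts.SP_M, counts.SP_H, counts.SP_T) == (0, 0, 0, 12)

    def test_one_superpixel_per_bin(self):
        counts = _counts_from_means(np.array([0.1, 0.3, 0.5, 0.9]))
        assert (counts.SP_W, counts.SP_M, counts.SP_H, counts.SP_T) == (1, 1, 1, 4)

    def test_tie_at_threshold_is_lower_inclusive(self):
        counts = _counts_from_means(np.array([0.4]))  # exactly t_moderate
        assert counts.SP_M == 1 and counts.SP_W == 0

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            IntensityThresholds(0.4, 0.2, 0.8)

    def test_quantile_helper_orders_thresholds(self, rng):
        t = thresholds_from_quantiles(rng.exponential(0.1, 10000))
        assert 0 <= t.t_weak < t.t_moderate < t.t_strong


def _counts_from_means(means):
    from dabquant.hscore import SuperpixelMap

    n = len(means)
    labels = np.arange(1, n + 1).reshape(1, n)
    spmap = SuperpixelMap(labels, n, np.asarray(means, float), np.ones(n, int))
    return classify_superpixels(spmap, THRESH)


class TestHScore:
    def test_endpoints(self):
        assert hscore(ClassCounts(0, 0, 8, 8)).hscore == 300.0
        assert hscore(ClassCounts(0, 0, 0, 8)).hscore == 0.0
        assert hscore(ClassCounts(8, 0, 0, 8)).hscore == 100.0
        assert hscore(ClassCounts(0, 8, 0, 8)).hscore == 200.0

    def test_printed_formula_example(self):
        res = hscore(ClassCounts(SP_W=2, SP_M=1, SP_H=1, SP_T=8))
        assert res.hscore == pytest.approx(87.5)
        assert res.fractions["negative"] == pytest.approx(0.5)

    def test_undefined_for_zero_total(self):
        with pytest.raises(ValueError):
            hscore(ClassCounts(0, 0, 0, 0))

    def test_counts_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            ClassCounts(5, 5, 5, 8)

    @settings(max_examples=50, derandomize=True, database=None)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_bounds_property(self, n_neg, w, m, h):
        """0 ≤ H ≤ 300; endpoints only at all-negative / all-strong."""
        total = n_neg + w + m + h
        if total == 0:
            return
        res = hscore(ClassCounts(w, m, h, total))
        assert 0 <= res.hscore <= 300
        if res.hscore == 300:
            assert h == total
        if res.hscore == 0:
            assert w == m == h == 0

    def test_monotone_in_constant_od_shift(self, rng):
        """Adding a constant to all ODs never decreases the H-score."""
        values = rng.uniform(0, 0.5, (40, 40))
        roi = np.ones((40, 40), bool)
        params = SlicParams(target_diameter=8)
        base, _, _ = hscore_roi(ODChannel(values, 1.0), roi, THRESH, params)
        for shift in (0.1, 0.3):
            shifted, _, _ = hscore_roi(ODChannel(values + shift, 1.0), roi, THRESH, params)
            assert shifted.hscore >= base.hscore

    def test_matches_brute_force_oracle(self, rng):
        """Classification + H-score equal an independent per-label reimplementation."""
        for _ in range(5):
            side = int(rng.integers(16, 33))
            values = rng.uniform(0, 1, (side, side))
            roi = np.ones((side, side), bool)
            spmap = slic_segment(ODChannel(values, 1.0), roi, SlicParams(target_diameter=6))
            got = hscore(classify_superpixels(spmap, THRESH)).hscore
            assert got == brute_force_hscore(values, spmap.labels, THRESH)

    def test_closure_with_generator(self):
        """Generated class-area fractions recovered ±2pp at 10 µm superpixels.

        Uses a 192 µm tile (~360 superpixels): the ROI must hold enough
        superpixels for count fractions to resolve a 2-point tolerance.
        """
        spec = scene_for_metric("AT8_hscore", 90.0, image_size=(768, 768), seed=21)
        image, truth = render_scene(spec)
        dab = deconvolve_dab(rgb_to_od(image), StainVectors.hdab(), image.pixel_size)
        roi = np.ones(image.shape, bool)
        _, counts, _ = hscore_roi(dab, roi, GENERATION_THRESHOLDS)
        for name, frac in counts.fractions().items():
            assert abs(frac - truth.class_area_fractions[name]) < 0.02


class TestIntensityDistribution:
    def test_identical_groups_no_difference(self):
        counts = [ClassCounts(2, 3, 1, 10) for _ in range(4)]
        df = intensity_distribution({"a": counts, "b": list(counts)})
        assert np.allclose(df["difference"], 0.0)
        assert (df["p"] == 1.0).all()

    def test_reclassification_shifts_negative_to_moderate(self):
        """Moving negatives to moderate raises the moderate fraction by the
        same amount the negative fraction falls; strong unchanged."""
        group_a = [ClassCounts(2, 2, 1, 10) for _ in range(5)]
        group_b = [ClassCounts(2, 5, 1, 10) for _ in range(5)]  # 3 negatives → moderate
        df = intensity_distribution({"a": group_a, "b": group_b}).set_index("class")
        assert df.loc["negative", "difference"] == pytest.approx(0.3)
        assert df.loc["moderate", "difference"] == pytest.approx(-0.3)
        assert df.loc["strong", "difference"] == pytest.approx(0.0)
        assert df.loc["weak", "difference"] == pytest.approx(0.0)

    def test_single_mouse_reports_without_significance(self):
        df = intensity_distribution(
            {"a": [ClassCounts(1, 1, 1, 4)], "b": [ClassCounts(0, 0, 4, 4)]}
        )
        assert (df["stars"] == "ns").all()

    def test_mismatched_group_count_rejected(self):
        with pytest.raises(ValueError):
            intensity_distribution({"a": [ClassCounts(0, 0, 0, 4)]})
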