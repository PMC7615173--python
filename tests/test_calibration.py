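"""Calibration binning, ECE oracle equivalence, segmentation metrics."""

import numpy as np
import pytest

from mismatch.calibration import (bin_pixels, iou_ece_trend,
                                  reliability_diagram_data,
                                  segmentation_metrics)


def brute_force_ece(p, y, M=5):
    """Independent per-pixel recomputation of the binned calibration gap."""
    p, y = np.ravel(p), np.ravel(y).astype(bool)
    conf = np.maximum(p, 1 - p)
    correct = (p >= 0.5) == y
    edges = np.linspace(0.5, 1.0, M + 1)
    ece = 0.0
    for m in range(M):
        if m == 0:
            members = conf <= edges[1]
        else:
            members = (conf > edges[m]) & (conf <= edges[m + 1])
        if not members.any():
            continue
        acc = correct[members].mean()
        avg_conf = conf[members].mean()
        ece += members.sum() / p.size * abs(acc - avg_conf)
    return ece


class TestBinning:
    def test_perfect_binary_prediction_has_zero_ece(self):
        y = (np.random.default_rng(0).random((16, 16)) > 0.7)
        report = bin_pixels(y.astype(float), y)
        assert report.ece == pytest.approx(0.0, abs=1e-15)
        occupied = report.counts > 0
        np.testing.assert_allclose(report.accuracy[occupied], 1.0)
        np.testing.assert_allclose(report.confidence[occupied], 1.0)

    def test_single_bin_hand_example(self):
        # 10 pixels at confidence 0.9, 8 of them correct: ECE = |0.8-0.9|
        p = np.full(10, 0.9)
        y = np.array([1] * 8 + [0] * 2)
        report = bin_pixels(p, y)
        assert (report.counts > 0).sum() == 1
        assert report.ece == pytest.approx(0.1, abs=1e-12)

    def test_two_bin_hand_example(self):
        # 4 px at 0.6 (2 correct) and 6 px at 0.95 (all correct):
        # 0.4*|0.5-0.6| + 0.6*|1-0.95| = 0.07
        p = np.array([0.6] * 4 + [0.95] * 6)
        y = np.array([1, 1, 0, 0] + [1] * 6)
        report = bin_pixels(p, y)
        assert report.ece == pytest.approx(0.07, abs=1e-12)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.random((32, 32))
            y = rng.random((32, 32)) > rng.random()
            got = bin_pixels(p, y).ece
            assert got == pytest.approx(brute_force_ece(p, y), abs=1e-12)

    def test_invariant_to_pixel_ordering(self):
        rng = np.random.default_rng(8)
        p = rng.random(500)
        y = rng.random(500) > 0.4
        perm = rng.permutation(500)
        assert bin_pixels(p, y).ece == pytest.approx(
            bin_pixels(p[perm], y[perm]).ece, abs=1e-15)

    def test_counts_partition_all_pixels(self):
        rng = np.random.default_rng(9)
        p = rng.random((20, 20))
        report = bin_pixels(p, rng.random((20, 20)) > 0.5)
        assert report.counts.sum() == report.n_pixels == 400

    def test_edge_ties_go_to_lower_bin(self):
        # confidence exactly 0.6 is the upper edge of bin 1 of [0.5, 1]
        report = bin_pixels(np.array([0.6]), np.array([1]))
        assert report.counts[0] == 1 and report.counts[1:].sum() == 0

    def test_ece_bounded_by_max_bin_gap(self):
        rng = np.random.default_rng(10)
        p = rng.random(1000)
        y = rng.random(1000) > 0.3
        report = bin_pixels(p, y)
        occ = report.counts > 0
        assert report.ece <= np.abs(report.accuracy[occ]
                                    - report.confidence[occ]).max() + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_pixels(np.empty(0), np.empty(0))


class TestReliabilityDiagram:
    def test_hand_example_rows(self):
        p = np.array([0.6] * 4 + [0.95] * 6)
        y = np.array([1, 1, 0, 0] + [1] * 6)
        table = reliability_diagram_data(bin_pixels(p, y))
        assert len(table) == 5
        first = table.iloc[0]
        assert first["accuracy"] == pytest.approx(0.5)
        assert first["confidence"] == pytest.approx(0.6)
        last = table.iloc[4]
        assert last["accuracy"] == pytest.approx(1.0)
        assert last["confidence"] == pytest.approx(0.95)
        assert table["empty"].sum() == 3

    def test_perfect_calibration_has_equal_bars(self):
        y = np.random.default_rng(2).random((8, 8)) > 0.5
        table = reliability_diagram_data(bin_pixels(y.astype(float), y))
        occupied = table[~table["empty"]]
        np.testing.assert_allclose(occupied["accuracy"], occupied["confidence"])


class TestSegmentationMetrics:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool); m[3:7, 3:7] = True
        got = segmentation_metrics(m, m)
        assert got == {"iou": 1.0, "dice": 1.0, "hausdorff": 0.0, "asd": 0.0}

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool); a[:2] = True
        b = np.zeros((10, 10), bool); b[8:] = True
        assert segmentation_metrics(a, b)["iou"] == 0.0

    def test_half_overlap_set_arithmetic(self):
        a = np.zeros((8, 8), bool); a[0, :4] = True
        b = np.zeros((8, 8), bool); b[0, 2:6] = True
        got = segmentation_metrics(a, b)
        assert got["iou"] == pytest.approx(2 / 6)
        assert got["dice"] == pytest.approx(0.5)

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.random((12, 12)) > 0.6
            b = rng.random((12, 12)) > 0.6
            got = segmentation_metrics(a, b)
            assert got["dice"] >= got["iou"]
            assert got["dice"] == pytest.approx(
                2 * got["iou"] / (1 + got["iou"]), abs=1e-12)

    def test_empty_vs_empty_is_perfect(self):
        e = np.zeros((5, 5), bool)
        got = segmentation_metrics(e, e)
        assert got["iou"] == 1.0 and got["hausdorff"] == 0.0

    def test_one_empty_mask_warns_and_returns_infinite_distance(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool); b[2, 2] = True
        with pytest.warns(UserWarning):
            got = segmentation_metrics(a, b)
        assert got["iou"] == 0.0 and np.isinf(got["hausdorff"])

    def test_spacing_scales_distances(self):
        a = np.zeros((9, 9), bool); a[4, 2] = True
        b = np.zeros((9, 9), bool); b[4, 6] = True
        unit = segmentation_metrics(a, b)
        scaled = segmentation_metrics(a, b, spacing=(1.0, 2.5))
        assert scaled["hausdorff"] == pytest.approx(2.5 * unit["hausdorff"])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestIouEceTrend:
    def test_quadratic_fit_recovers_known_slope(self):
        ece = np.linspace(0.01, 0.3, 40)
        iou = 0.9 - 1.5 * ece + 0.2 * ece ** 2
        got = iou_ece_trend(iou, ece)
        slope = 2 * 0.2 * ece.mean() - 1.5
        assert got["slope_at_mean_ece"] == pytest.approx(slope, abs=1e-9)
        assert got["slope_magnitude"] == pytest.approx(abs(slope), abs=1e-9)

    def test_flat_relation_has_smaller_slope_than_steep(self):
        rng = np.random.default_rng(4)
        ece = rng.random(60) * 0.3
        flat = 0.8 - 0.1 * ece + rng.normal(0, 0.005, 60)
        steep = 0.8 - 2.0 * ece + rng.normal(0, 0.005, 60)
        assert (iou_ece_trend(flat, ece)["slope_magnitude"]
                < iou_ece_trend(steep, ece)["slope_magnitude"])

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            iou_ece_trend([0.5, 0.6], [0.1, 0.2])
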