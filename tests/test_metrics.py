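import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmjjsw import (
    ConfusionCounts,
    confusion_counts,
    dice,
    evaluate_case,
    hausdorff_mm,
    precision,
    recall,
    summarize,
    volume_similarity,
)

from oracles import brute_confusion, brute_hausdorff, random_mask


class TestConfusionCounts:
    def test_identity_masks_have_no_errors(self):
        m = random_mask(np.random.default_rng(0))
        for code in (1, 2, 3):
            c = confusion_counts(m, m, code)
            assert c.fp == 0 and c.fn == 0

    def test_overlap_arithmetic(self):
        pred = np.zeros((4, 4), dtype=np.uint8)
        ref = np.zeros((4, 4), dtype=np.uint8)
        pred[0, 0:4] = 1          # 4 predicted px
        ref[0, 1:4] = 1           # overlap 3
        ref[1, 0:3] = 1           # 6 reference px total
        assert confusion_counts(pred, ref, 1) == ConfusionCounts(3, 1, 3)

    def test_empty_prediction(self):
        pred = np.zeros((3, 3), dtype=np.uint8)
        ref = np.zeros((3, 3), dtype=np.uint8)
        ref[0, 0:3] = 2
        ref[1, 0:2] = 2
        assert confusion_counts(pred, ref, 2) == ConfusionCounts(0, 0, 5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)), 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pixel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred, ref = random_mask(rng), random_mask(rng)
        for code in (1, 2, 3):
            c = confusion_counts(pred, ref, code)
            assert (c.tp, c.fp, c.fn) == brute_confusion(pred, ref, code)


class TestRatioMetrics:
    def test_dice_example(self):
        assert dice(ConfusionCounts(3, 1, 3)) == pytest.approx(0.6)

    def test_dice_conventions(self):
        assert dice(ConfusionCounts(0, 0, 0)) == 1.0     # empty vs empty
        assert dice(ConfusionCounts(0, 0, 5)) == 0.0     # missed structure
        assert dice(ConfusionCounts(0, 4, 0)) == 0.0     # hallucinated structure

    def test_precision_recall_examples(self):
        c = ConfusionCounts(3, 1, 3)
        assert precision(c) == pytest.approx(0.75)
        assert recall(c) == pytest.approx(0.5)
        assert precision(ConfusionCounts(5, 0, 2)) == 1.0
        assert math.isnan(precision(ConfusionCounts(0, 0, 3)))
        assert math.isnan(recall(ConfusionCounts(0, 3, 0)))

    def test_volume_similarity_examples(self):
        assert volume_similarity(4, 6) == pytest.approx(0.8)
        assert volume_similarity(7, 7) == 1.0
        assert volume_similarity(0, 9) == 0.0
        assert volume_similarity(0, 0) == 1.0

    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, derandomize=True)
    def test_dice_is_harmonic_mean_of_precision_recall(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, fn)
        p, r = precision(c), recall(c)
        if not (math.isnan(p) or math.isnan(r)) and p + r > 0:
            assert dice(c) == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, derandomize=True)
    def test_volume_similarity_bounds_dice(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, fn)
        assert 0.0 <= dice(c) <= 1.0
        assert volume_similarity(tp + fp, tp + fn) >= dice(c) - 1e-12


class TestHausdorff:
    def test_identical_masks_give_zero(self):
        m = random_mask(np.random.default_rng(1))
        for code in (1, 2, 3):
            if (m == code).any():
                assert hausdorff_mm(m, m, code) == 0.0

    def test_three_four_five_triangle(self):
        pred = np.zeros((6, 6), dtype=np.uint8)
        ref = np.zeros((6, 6), dtype=np.uint8)
        pred[0, 0] = 1
        ref[3, 4] = 1
        assert hausdorff_mm(pred, ref, 1) == pytest.approx(5.0)

    def test_physical_spacing_scales_distances(self, make_mask):
        pred = np.zeros((6, 6), dtype=np.uint8)
        ref = np.zeros((6, 6), dtype=np.uint8)
        pred[0, 0] = 1
        ref[4, 0] = 1
        a = make_mask(pred, spacing_mm=(0.5, 0.5))
        b = make_mask(ref, spacing_mm=(0.5, 0.5))
        assert hausdorff_mm(a, b, 1) == pytest.approx(2.0)

    def test_empty_side_conventions(self):
        empty = np.zeros((5, 5), dtype=np.uint8)
        nonempty = empty.copy()
        nonempty[2, 2] = 1
        assert hausdorff_mm(empty, empty, 1) == 0.0
        assert math.isnan(hausdorff_mm(empty, nonempty, 1))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred, ref = random_mask(rng), random_mask(rng)
        for code in (1, 2, 3):
            expected = brute_hausdorff(pred, ref, code)
            got = hausdorff_mm(pred, ref, code)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)
                assert hausdorff_mm(ref, pred, code) == pytest.approx(expected, abs=1e-12)


class TestCaseEvaluation:
    def test_perfect_prediction_scores_one(self, make_mask):
        m = make_mask(random_mask(np.random.default_rng(2)), id="c0")
        rep = evaluate_case(m, m)
        for cls in ("MC", "JS", "GF"):
            assert rep[cls]["dice"] == 1.0 and rep[cls]["vs"] == 1.0
            assert rep[cls]["hd_mm"] == 0.0

    def test_summary_mean_and_sample_sd(self):
        reports = [
            {"id": "a", "MC": {"dice": 0.6, "precision": 1, "recall": 1, "vs": 1, "hd_mm": 0},
             "JS": {"dice": 1, "precision": 1, "recall": 1, "vs": 1, "hd_mm": 0},
             "GF": {"dice": 1, "precision": 1, "recall": 1, "vs": 1, "hd_mm": 0}},
            {"id": "b", "MC": {"dice": 0.8, "precision": 1, "recall": 1, "vs": 1, "hd_mm": 0},
             "JS": {"dice": 1, "precision": 1, "recall": 1, "vs": 1, "hd_mm": 0},
             "GF": {"dice": 1, "precision": 1, "recall": 1, "vs": 1, "hd_mm": 0}},
        ]
        summary = summarize(reports)
        mc = summary[summary["class"] == "MC"].iloc[0]
        assert mc.dice_mean == pytest.approx(0.7)
        assert mc.dice_sd == pytest.approx(0.14142135, abs=1e-6)

    def test_undefined_values_excluded_and_counted(self, make_mask):
        pred = np.zeros((8, 8), dtype=np.uint8)
        ref = np.zeros((8, 8), dtype=np.uint8)
        ref[0:2, 0:2] = 3  # GF missed entirely: HD undefined for this case
        pred[4, 4] = 1
        ref[4, 4] = 1
        reports = [evaluate_case(make_mask(pred), make_mask(ref), case_id="x")]
        summary = summarize(reports)
        gf = summary[summary["class"] == "GF"].iloc[0]
        assert gf.hd_mm_n_excluded == 1
        assert gf.dice_mean == 0.0  # the 0.00 Dice convention for a missed structure

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
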