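"""Overlap metrics against brute-force oracles; agreement closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcvbmd.errors import DegenerateDataError, ShapeError
from mcvbmd.evaluate import (agreement_stats, auroc, dsc, iou, pixel_accuracy,
                             summarize_runs)


def brute_force_auroc(scores, labels):
    """Pair enumeration: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        x = rng.random((6, 6, 3)) > 0.4
        assert dsc(x, x) == 1.0
        assert iou(x, x) == 1.0
        assert pixel_accuracy(x, x) == 1.0

    def test_counted_examples(self):
        x = np.zeros(16, bool)
        y = np.zeros(16, bool)
        x[:8] = True
        y[4:12] = True  # |X|=|Y|=8, intersection 4, union 12
        assert dsc(x, y) == pytest.approx(0.5)
        assert iou(x, y) == pytest.approx(1 / 3)

    def test_disjoint_and_empty_conventions(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4] = True
        b[4:] = True
        assert dsc(a, b) == 0.0 and iou(a, b) == 0.0
        empty = np.zeros(8, bool)
        assert dsc(empty, empty) == 1.0 and iou(empty, empty) == 1.0
        assert dsc(a, empty) == 0.0 and iou(a, empty) == 0.0

    def test_accuracy_hand_count(self):
        x = np.array([[1, 0], [1, 0]], bool)  # TP=1, TN=2, FP=1 vs y
        y = np.array([[1, 0], [0, 0]], bool)
        assert pixel_accuracy(x, y) == 0.75

    def test_all_background_prediction_accuracy(self):
        y = np.zeros(1000, bool)
        y[:10] = True
        assert pixel_accuracy(np.zeros(1000, bool), y) == pytest.approx(0.99)

    def test_symmetry(self, rng):
        x = rng.random((5, 5)) > 0.5
        y = rng.random((5, 5)) > 0.5
        assert dsc(x, y) == dsc(y, x)
        assert iou(x, y) == iou(y, x)
        assert pixel_accuracy(x, y) == pixel_accuracy(y, x)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            dsc(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_metrics_match_bruteforce_counts_on_random_masks(self, rng):
        for _ in range(300):
            x = rng.random((4, 5)) > rng.random()
            y = rng.random((4, 5)) > rng.random()
            tp = int((x & y).sum())
            fp = int((x & ~y).sum())
            fn = int((~x & y).sum())
            tn = int((~x & ~y).sum())
            if tp + fp + fn > 0:
                assert dsc(x, y) == pytest.approx(2 * tp / (2 * tp + fp + fn))
                assert iou(x, y) == pytest.approx(tp / (tp + fp + fn))
            assert pixel_accuracy(x, y) == pytest.approx((tp + tn) / 20)

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=60, deadline=None)
    def test_jaccard_dice_identity(self, seed):
        gen = np.random.default_rng(seed)
        x = gen.random((6, 6)) > gen.random()
        y = gen.random((6, 6)) > gen.random()
        d = dsc(x, y)
        assert iou(x, y) == pytest.approx(d / (2.0 - d), abs=1e-12)
        assert iou(x, y) <= d + 1e-12


class TestAUROC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        assert auroc(scores, labels) == 1.0

    def test_constant_scores(self):
        scores = np.full(10, 0.5)
        labels = np.arange(10) < 4
        assert auroc(scores, labels) == 0.5

    def test_worked_pair_enumeration_example(self):
        scores = np.array([0.9, 0.8, 0.8, 0.1])
        labels = np.array([True, True, False, False])
        # pairs: (.9>.8)=1, (.9>.1)=1, (.8==.8)=.5, (.8>.1)=1 -> 3.5/4
        assert auroc(scores, labels) == pytest.approx(0.875)
        assert brute_force_auroc(scores, labels) == pytest.approx(0.875)

    def test_matches_bruteforce_on_small_grids(self, rng):
        for _ in range(100):
            scores = rng.random(rng.integers(5, 100))
            labels = rng.random(scores.size) > 0.5
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateDataError):
            auroc(np.array([0.1, 0.2]), np.array([True, True]))


class TestSummarizeRuns:
    def test_mean_and_sd_hand_arithmetic(self):
        table = summarize_runs({"2d": [{"dsc": 0.933}, {"dsc": 0.937},
                                       {"dsc": 0.943}]})
        row = table.iloc[0]
        assert row["dsc_mean"] == pytest.approx(0.9377, abs=5e-5)
        assert row["dsc_sd"] == pytest.approx(0.00503, abs=5e-5)

    def test_single_run_has_no_sd(self):
        row = summarize_runs({"pre": [{"dsc": 0.972}]}).iloc[0]
        assert row["dsc_mean"] == pytest.approx(0.972)
        assert np.isnan(row["dsc_sd"])

    def test_equal_runs_zero_sd(self):
        row = summarize_runs({"x": [{"iou": 0.9}] * 3}).iloc[0]
        assert row["iou_sd"] == 0.0


class TestAgreementStats:
    def test_perfect_agreement(self, rng):
        values = rng.normal(280, 40, 10)
        report = agreement_stats(values, values.copy())
        assert report.pearson_r == pytest.approx(1.0)
        assert report.spearman_rho == pytest.approx(1.0)
        assert report.icc == pytest.approx(1.0)
        assert report.bland_altman_mean_diff == 0.0
        assert report.bland_altman_loa_low == report.bland_altman_loa_high == 0.0

    def test_constant_offset_closed_forms(self, rng):
        manual = rng.normal(280, 40, 12)
        report = agreement_stats(manual, manual + 10.0)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.bland_altman_mean_diff == pytest.approx(10.0)
        assert report.bland_altman_loa_high - report.bland_altman_loa_low \
            == pytest.approx(0.0, abs=1e-9)
        assert report.icc < 1.0

    def test_proportional_pairs_hand_arithmetic(self):
        manual = np.array([1.0, 2.0, 3.0])
        automatic = np.array([2.0, 4.0, 6.0])
        report = agreement_stats(manual, automatic)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.spearman_rho == pytest.approx(1.0)
        # difference direction is automatic - manual: mean(2x - x) = +2
        assert report.bland_altman_mean_diff == pytest.approx(2.0)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            agreement_stats(np.full(5, 3.0), np.arange(5, dtype=float))

    def test_too_few_pairs_raises(self):
        with pytest.raises(DegenerateDataError):
            agreement_stats([1.0, 2.0], [1.0, 2.0])

    def test_limits_cover_95_percent_of_gaussian_differences(self):
        gen = np.random.default_rng(7)
        manual = gen.normal(280, 40, 4000)
        automatic = manual + gen.normal(-5, 8, 4000)
        report = agreement_stats(manual, automatic)
        diffs = automatic - manual
        covered = np.mean((diffs >= report.bland_altman_loa_low)
                          & (diffs <= report.bland_altman_loa_high))
        assert covered == pytest.approx(0.95, abs=0.02)

    def test_icc_variant_selection(self, rng):
        manual = rng.normal(280, 40, 15)
        automatic = manual + 20.0 + rng.normal(0, 2, 15)
        absolute = agreement_stats(manual, automatic, icc_form="ICC2").icc
        consistency = agreement_stats(manual, automatic, icc_form="ICC3").icc
        # a constant offset hurts absolute agreement, not consistency
        assert absolute < consistency
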