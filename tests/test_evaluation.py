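"""Study partitioning, confusion metrics, ROC/AUC, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hasdetect.evaluation import (
    ConfusionMetrics,
    EnergyThresholdBaseline,
    build_kfold,
    build_loocv_schemes,
    confusion,
    mean_roc,
    roc_auc,
    summarize_study,
)

# Published confusion rows (TP, FP, FN, TN, sensitivity, selectivity,
# precision, accuracy) for the three detectors x 11 schemes/folds each.
REFERENCE_CONFUSION_ROWS = [
    # scalogram-image detector
    (1636, 8, 29, 8851, 98.26, 99.91, 99.51, 99.65),
    (1044, 259, 27, 8833, 97.48, 97.15, 80.12, 97.19),
    (938, 70, 5, 4420, 99.47, 98.44, 93.06, 98.62),
    (1623, 21, 15, 8865, 99.08, 99.76, 98.72, 99.66),
    (1048, 255, 9, 8851, 99.15, 97.20, 80.43, 97.40),
    (938, 70, 5, 4420, 99.47, 98.44, 93.06, 98.62),
    (780, 11, 2, 5410, 99.74, 99.80, 98.61, 99.79),
    (783, 8, 10, 5402, 98.74, 99.85, 98.99, 99.71),
    (786, 5, 7, 5405, 99.12, 99.91, 99.37, 99.81),
    (786, 5, 7, 5405, 99.12, 99.91, 99.37, 99.81),
    (785, 6, 7, 5405, 99.12, 99.89, 99.24, 99.79),
    # wavelet-Fourier matrix detector
    (1628, 16, 7, 8873, 99.57, 99.82, 99.03, 99.78),
    (1030, 273, 57, 8803, 94.76, 96.99, 79.05, 96.75),
    (958, 50, 6, 4419, 99.38, 98.88, 95.04, 98.97),
    (1615, 29, 5, 8875, 99.69, 99.67, 98.24, 99.68),
    (1041, 262, 109, 8751, 90.52, 97.09, 79.89, 96.35),
    (915, 93, 1, 4424, 99.89, 97.94, 90.77, 98.27),
    (773, 18, 6, 5406, 99.23, 99.67, 97.72, 99.61),
    (781, 10, 6, 5406, 99.24, 99.82, 98.74, 99.74),
    (780, 11, 7, 5405, 99.11, 99.80, 98.61, 99.71),
    (785, 6, 3, 5409, 99.62, 99.89, 99.24, 99.85),
    (776, 15, 1, 5411, 99.87, 99.72, 98.10, 99.74),
    # raw-signal detector
    (1610, 34, 70, 8810, 95.83, 99.62, 97.93, 99.01),
    (1048, 255, 79, 8781, 92.99, 97.18, 80.43, 96.71),
    (916, 92, 1, 4424, 99.89, 97.96, 90.87, 98.29),
    (1554, 90, 221, 8659, 87.55, 98.97, 94.53, 97.04),
    (1046, 257, 53, 8807, 95.18, 97.16, 80.28, 96.95),
    (946, 62, 0, 4425, 100.00, 98.62, 93.85, 98.86),
    (782, 9, 9, 5403, 98.86, 99.83, 98.86, 99.71),
    (776, 15, 14, 5398, 98.23, 99.72, 98.10, 99.53),
    (783, 8, 19, 5393, 97.63, 99.85, 98.99, 99.56),
    (785, 6, 7, 5405, 99.12, 99.89, 99.24, 99.79),
    (788, 3, 3, 5409, 99.62, 99.94, 99.62, 99.90),
]


class TestLoocvSchemes:
    def test_reference_counts_study1(self, table3_manifest):
        y = (table3_manifest["label"] == "HAS").to_numpy().astype(int)
        schemes = build_loocv_schemes(table3_manifest, include_sham=True)
        counts = [s.counts(y) for s in schemes]
        assert counts[0]["train"] == (20_491, 2311, 18_180)
        assert counts[0]["test"] == (10_524, 1644, 8880)
        assert round(counts[0]["training_to_testing_ratio"], 2) == 1.95
        assert counts[1]["train"] == (20_852, 2652, 18_200)
        assert counts[2]["train"] == (25_582, 2947, 22_635)

    def test_reference_counts_study2(self, table3_manifest):
        y = (table3_manifest["label"] == "HAS").to_numpy().astype(int)
        schemes = build_loocv_schemes(table3_manifest, include_sham=False)
        counts = [s.counts(y) for s in schemes]
        assert counts[0]["train"] == (15_596, 2311, 13_285)
        assert counts[1]["train"] == (15_957, 2652, 13_305)
        assert counts[2]["train"] == (20_687, 2947, 17_740)

    def test_sham_never_in_study2_and_always_trains_in_study1(self, table3_manifest):
        groups = table3_manifest["group"].to_numpy()
        for s in build_loocv_schemes(table3_manifest, include_sham=True):
            assert "G3" in s.train_groups
            assert "G3" not in s.test_groups
        for s in build_loocv_schemes(table3_manifest, include_sham=False):
            assert not np.any(groups[s.train_idx] == "G3")
            assert not np.any(groups[s.test_idx] == "G3")

    def test_missing_group_rejected(self, table3_manifest):
        with pytest.raises(ValueError, match="missing"):
            build_loocv_schemes(table3_manifest[table3_manifest.group != "G2"])


class TestKfold:
    def test_reference_fold_counts(self, table3_manifest):
        y = (table3_manifest["label"] == "HAS").to_numpy().astype(int)
        for s in build_kfold(table3_manifest, k=5, seed=0):
            assert s.counts(y)["test"] == (6203, 791, 5412)
            assert s.counts(y)["train"] == (24_812, 3164, 21_648)

    def test_folds_partition_dataset(self, table3_manifest):
        schemes = build_kfold(table3_manifest, k=5, seed=0)
        covered = np.sort(np.concatenate([s.test_idx for s in schemes]))
        assert np.array_equal(covered, np.arange(len(table3_manifest)))
        for s in schemes:
            assert np.intersect1d(s.train_idx, s.test_idx).size == 0

    def test_fixed_seed_reproduces_membership(self, table3_manifest):
        a = build_kfold(table3_manifest, k=5, seed=4)
        b = build_kfold(table3_manifest, k=5, seed=4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.test_idx, sb.test_idx)

    def test_k_below_two_rejected(self, table3_manifest):
        with pytest.raises(ValueError):
            build_kfold(table3_manifest, k=1)


class TestConfusionMetrics:
    @pytest.mark.parametrize("row", REFERENCE_CONFUSION_ROWS)
    def test_reference_rows_recompute_at_two_decimals(self, row):
        tp, fp, fn, tn, sens, sel, prec, acc = row
        m = ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
        assert round(m.sensitivity, 2) == sens
        assert round(m.selectivity, 2) == sel
        assert round(m.precision, 2) == prec
        assert round(m.accuracy, 2) == acc

    def test_counts_from_label_prediction_pairs(self):
        labels = [1, 1, 0, 0, 1, 0]
        preds = [1, 0, 0, 1, 1, 0]
        m = confusion(labels, preds)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 1, 2)
        assert m.total == 6

    def test_all_correct_toy_set(self):
        m = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert m.accuracy == 100.0
        assert m.fp == m.fn == 0

    def test_zero_denominator_gives_nan(self):
        m = confusion([0, 0], [0, 0])
        assert np.isnan(m.sensitivity)
        assert np.isnan(m.precision)
        assert m.selectivity == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_identities_hold_for_all_inputs(self, pairs):
        labels = [int(a) for a, _ in pairs]
        preds = [int(b) for _, b in pairs]
        m = confusion(labels, preds)
        assert m.total == len(pairs)
        if m.tp + m.fn:
            assert m.sensitivity == pytest.approx(100 * m.tp / (m.tp + m.fn))
        assert m.accuracy == pytest.approx(100 * (m.tp + m.tn) / m.total)


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        assert roc_auc(scores, labels).auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.03

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_equals_pairwise_comparison_oracle(self, data):
        """Trapezoidal AUC equals the Mann-Whitney pairwise statistic."""
        n = data.draw(st.integers(4, 60))
        scores = np.asarray(
            data.draw(
                st.lists(
                    st.floats(0, 1, allow_nan=False), min_size=n, max_size=n
                )
            )
        )
        labels = np.asarray(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        pos, neg = scores[labels], scores[~labels]
        oracle = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert roc_auc(scores, labels.astype(int)).auc == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [1, 1])

    def test_mean_roc_band_shape(self):
        rng = np.random.default_rng(1)
        curves = []
        for i in range(3):
            s = rng.random(100)
            l = (s + rng.normal(0, 0.3, 100) > 0.5).astype(int)
            if np.unique(l).size < 2:
                continue
            curves.append(roc_auc(s, l))
        grid, mean_tpr, sd_tpr = mean_roc(curves)
        assert grid.shape == mean_tpr.shape == sd_tpr.shape
        assert mean_tpr[0] <= mean_tpr[-1]


class TestSummaries:
    def test_reference_study1_average(self):
        rows = [ConfusionMetrics(*r[:4]) for r in REFERENCE_CONFUSION_ROWS[:3]]
        s = summarize_study(rows)
        assert round(s["accuracy_mean"], 1) == 98.5

    def test_single_row_has_zero_sd(self):
        s = summarize_study([ConfusionMetrics(10, 1, 1, 10, auc=0.9)])
        assert s["accuracy_sd"] == 0.0

    def test_permutation_invariant(self):
        rows = [ConfusionMetrics(*r[:4]) for r in REFERENCE_CONFUSION_ROWS[:5]]
        assert summarize_study(rows) == summarize_study(rows[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_study([])


class TestEnergyBaseline:
    def test_thresholds_separable_rms(self):
        class Seg:
            def __init__(self, a):
                self.samples = np.full(100, a, dtype=float)

        segs = [Seg(1.0)] * 10 + [Seg(10.0)] * 10
        y = [0] * 10 + [1] * 10
        bl = EnergyThresholdBaseline().fit(segs, y)
        np.testing.assert_array_equal(bl.predict(segs), y)
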