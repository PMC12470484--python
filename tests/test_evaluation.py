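"""Metric panel: confusion arithmetic, ranking metrics, calibration, CIs."""

import numpy as np
import pytest

from afscreen import (
    ConfusionMatrix,
    auroc,
    bootstrap_ci,
    calibration,
    confusion,
    metrics_from_confusion,
    pr_auc,
    subgroup_metrics,
)
from afscreen.evaluation import round_half_up


class TestConfusion:
    def test_all_correct(self):
        cm = confusion([1, 1, 1, 0, 0], [1, 1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 0, 0)

    def test_all_false_positive(self):
        cm = confusion([1, 1, 1, 1], [0, 0, 0, 0])
        assert (cm.fp, cm.tp, cm.fn, cm.tn) == (4, 0, 0, 0)

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(0)
        pred, lab = rng.integers(0, 2, 100), rng.integers(0, 2, 100)
        cm = confusion(pred, lab)
        assert cm.total == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestMetricsFromConfusion:
    def test_published_confusion_matrix_reproduces_reported_metrics(self):
        """947/128/2186/8088 protocol counts give the reported screening
        metric panel to three decimals."""
        m = metrics_from_confusion(
            ConfusionMatrix(tp=947, fn=128, fp=2186, tn=8088)
        )
        rounded = {k: round_half_up(v) for k, v in m.items()}
        assert rounded == {
            "sensitivity": 0.881,
            "specificity": 0.787,
            "ppv": 0.302,
            "npv": 0.984,
            "accuracy": 0.796,
            "f1": 0.450,
        }

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=50, fp=0, fn=0, tn=50))
        assert all(v == 1.0 for v in m.values())

    def test_zero_sensitivity_zero_f1(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=3, fn=5, tn=2))
        assert m["sensitivity"] == 0.0
        assert m["f1"] == 0.0

    def test_zero_denominator_is_nan_marker(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert np.isnan(m["ppv"])

    def test_accuracy_prevalence_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pred, lab = rng.integers(0, 2, 60), rng.integers(0, 2, 60)
            if lab.sum() in (0, 60):
                continue
            cm = confusion(pred, lab)
            m = metrics_from_confusion(cm)
            pi = (cm.tp + cm.fn) / cm.total
            assert m["accuracy"] == pytest.approx(
                m["sensitivity"] * pi + m["specificity"] * (1 - pi)
            )


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_four_point_concordance(self):
        # exhaustive pair counting: 3 of 4 pairs concordant
        assert auroc([0.9, 0.6, 0.7, 0.2], [1, 1, 0, 0]) == 0.75

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 200))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            diff = pos[:, None] - neg[None, :]
            conc = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size
            assert auroc(scores, labels) == pytest.approx(conc)

    def test_null_is_half(self):
        rng = np.random.default_rng(3)
        a = auroc(rng.random(10000), rng.integers(0, 2, 10000))
        assert 0.47 < a < 0.53

    def test_single_class_undefined(self):
        assert np.isnan(auroc([0.5, 0.6], [1, 1]))


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_null_approaches_prevalence(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(20000) < 0.2).astype(int)
        assert pr_auc(rng.random(20000), labels) == pytest.approx(0.2, abs=0.02)

    def test_four_point_toy_against_enumeration(self):
        # hand enumeration of the step-wise average precision:
        # descending scores: (0.9, +), (0.8, -), (0.4, +), (0.2, -)
        # AP = 0.5*1 + 0.5*(2/3) = 5/6
        assert pr_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(5 / 6)

    def test_no_positives_undefined(self):
        assert np.isnan(pr_auc([0.5, 0.6], [0, 0]))


class TestCalibration:
    def test_self_calibrated_scores(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.02, 0.98, 50000)
        labels = (rng.random(50000) < scores).astype(int)
        intercept, slope = calibration(scores, labels)
        assert 0.95 <= slope <= 1.05
        assert -0.05 <= intercept <= 0.05

    def test_logit_shift_recovered(self):
        # closed form: scores whose logit is truth + 1 recalibrate with
        # slope 1 and intercept -1
        rng = np.random.default_rng(6)
        p = rng.uniform(0.05, 0.95, 50000)
        labels = (rng.random(50000) < p).astype(int)
        shifted = 1 / (1 + np.exp(-(np.log(p / (1 - p)) + 1.0)))
        intercept, slope = calibration(shifted, labels)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(-1.0, abs=0.07)

    def test_constant_scores_degenerate(self):
        i, s = calibration([0.5] * 10, [0, 1] * 5)
        assert np.isnan(i) and np.isnan(s)

    def test_extreme_scores_clipped_not_fatal(self):
        i, s = calibration([0.0, 1.0, 0.4, 0.7], [0, 1, 0, 1])
        assert np.isfinite(s) or np.isnan(s)


class TestBootstrap:
    def test_constant_statistic(self):
        lo, hi = bootstrap_ci(lambda x: float(np.mean(x)),
                              (np.full(50, 3.2),), n_boot=200, seed=0)
        assert lo == hi == pytest.approx(3.2)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        data = (rng.normal(size=100),)
        a = bootstrap_ci(np.mean, data, n_boot=300, seed=9)
        b = bootstrap_ci(np.mean, data, n_boot=300, seed=9)
        assert a == b

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(8)
        data = (rng.normal(size=300),)
        lo, hi = bootstrap_ci(np.mean, data, n_boot=500, seed=1)
        assert lo <= float(np.mean(data[0])) <= hi

    def test_coverage_of_sample_mean(self):
        # simulation oracle: the 95% percentile CI of a sample mean covers
        # the true mean at close to nominal rate
        rng = np.random.default_rng(9)
        hits = 0
        reps = 200
        for i in range(reps):
            sample = rng.normal(0.0, 1.0, 200)
            lo, hi = bootstrap_ci(np.mean, (sample,), n_boot=400, seed=i)
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / reps <= 0.99

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, (np.ones(5),), n_boot=10, seed=0)


class TestSubgroup:
    def test_reported_stroke_subgroup_rate(self):
        """468 of 551 prior-stroke AF patients flagged -> 0.849."""
        pred = np.concatenate([np.ones(468), np.zeros(83)]).astype(int)
        labels = np.ones(551, int)
        mask = np.ones(551, bool)
        out = subgroup_metrics(pred, labels, mask)
        assert round_half_up(out["detection_rate"]) == 0.849

    def test_all_positive_subgroup(self):
        out = subgroup_metrics([1, 1, 1], [1, 1, 1], [True, True, True])
        assert out["detection_rate"] == 1.0

    def test_counting_oracle_on_random_subgroup(self):
        rng = np.random.default_rng(10)
        pred = rng.integers(0, 2, 200)
        labels = rng.integers(0, 2, 200)
        mask = rng.random(200) < 0.3
        out = subgroup_metrics(pred, labels, mask)
        sel = mask & (labels == 1)
        assert out["detection_rate"] == pytest.approx(
            pred[sel].sum() / sel.sum()
        )

    def test_empty_subgroup_undefined(self):
        out = subgroup_metrics([1, 0], [1, 0], [False, False])
        assert np.isnan(out["detection_rate"])
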