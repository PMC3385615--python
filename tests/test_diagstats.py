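"""Diagnostic statistics: confusion rates, kappa, ROC/AUC, t-tests, CIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hepatex.diagstats import (
    ConfusionMatrix,
    GroupSummary,
    auc_significance,
    ci95,
    cohen_kappa,
    confusion_from_rates,
    confusion_metrics,
    convex_point,
    evaluate_cohort,
    roc_curve,
    two_sample_t,
)
from hepatex.exceptions import (
    EmptyRegionError,
    EvaluationError,
    UndefinedStatisticError,
)
from hepatex.texture_features import QVThresholds

from conftest import pair_counting_auc


class TestConfusionMetrics:
    def test_balanced_31_31(self):
        m = confusion_metrics(ConfusionMatrix(tp=26, fp=5, fn=5, tn=26))
        assert m["sensitivity"] == pytest.approx(26 / 31)
        assert m["specificity"] == pytest.approx(26 / 31)
        assert m["accuracy"] == pytest.approx(26 / 31)

    def test_high_specificity_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tp=26, fp=1, fn=5, tn=30))
        assert m["accuracy"] == pytest.approx(56 / 62)
        assert m["ppv"] == pytest.approx(26 / 27)
        assert m["npv"] == pytest.approx(30 / 35)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=31, fp=0, fn=0, tn=31))
        assert all(v == 1.0 for v in m.values())

    def test_undefined_rates_are_none(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=3))
        assert m["ppv"] is None
        assert m["npv"] is not None

    def test_empty_matrix_raises(self):
        with pytest.raises(EmptyRegionError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))


class TestKappa:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(26, 5, 5, 26), 0.677),
            (ConfusionMatrix(28, 4, 3, 27), 0.774),
            (ConfusionMatrix(26, 1, 5, 30), 0.806),
        ],
    )
    def test_published_agreement_values(self, cm, expected):
        assert cohen_kappa(cm) == pytest.approx(expected, abs=5e-4)

    def test_perfect_and_chance(self):
        assert cohen_kappa(ConfusionMatrix(31, 0, 0, 31)) == 1.0
        # predictions independent of truth: agreement exactly at chance
        assert cohen_kappa(ConfusionMatrix(15, 15, 15, 15)) == pytest.approx(0.0)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_balanced_groups_identity(self, tp, tn, n):
        """With equal true groups, kappa = 2 * accuracy - 1."""
        tp, tn = tp % (n + 1), tn % (n + 1)
        cm = ConfusionMatrix(tp=tp, fp=n - tn, fn=n - tp, tn=tn)
        acc = (tp + tn) / (2 * n)
        assert cohen_kappa(cm) == pytest.approx(2 * acc - 1)

    def test_confusion_from_rates_recovers_printed_tables(self):
        cm = confusion_from_rates(ppv=0.875, npv=0.900, accuracy=0.887, n_pos=31, n_neg=31)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (28, 4, 3, 27)
        cm = confusion_from_rates(ppv=0.963, npv=0.857, accuracy=0.903, n_pos=31, n_neg=31)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (26, 1, 5, 30)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve(scores_normal=[3, 4], scores_abnormal=[1, 2])
        assert roc.auc == pytest.approx(1.0)

    def test_interleaved_four_pairs(self):
        roc = roc_curve(scores_normal=[2, 4], scores_abnormal=[1, 3])
        assert roc.auc == pytest.approx(0.75)

    def test_identical_groups(self):
        roc = roc_curve(scores_normal=[1, 2, 3], scores_abnormal=[1, 2, 3])
        assert roc.auc == pytest.approx(0.5)

    def test_empty_group_raises(self):
        with pytest.raises(EvaluationError):
            roc_curve([], [1.0])

    def test_trapezoid_equals_pair_counting(self):
        """Mann-Whitney identity on 200 random score sets (with ties)."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n0 = int(rng.integers(2, 50))
            n1 = int(rng.integers(2, 50))
            # coarse grid forces ties
            normal = rng.integers(0, 12, size=n0).astype(float)
            abnormal = rng.integers(0, 12, size=n1).astype(float)
            roc = roc_curve(normal, abnormal)
            assert roc.auc == pytest.approx(pair_counting_auc(normal, abnormal))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        normal = rng.normal(3, 1, size=40)
        abnormal = rng.normal(1, 1, size=35)
        roc = roc_curve(normal, abnormal)
        y = [0] * 40 + [1] * 35
        # lower score => positive, so negate scores for sklearn's convention
        expected = roc_auc_score(y, -np.concatenate([normal, abnormal]))
        assert roc.auc == pytest.approx(expected)

    def test_label_swap_flips_auc(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 20)
        assert roc_curve(a, b).auc + roc_curve(b, a).auc == pytest.approx(1.0)


class TestConvexPoint:
    def test_perfect_separation_smallest_threshold(self):
        roc = roc_curve(scores_normal=[3, 4], scores_abnormal=[1, 2])
        assert convex_point(roc) == 2  # max abnormal score, smallest J=1 threshold

    def test_tie_broken_low(self):
        roc = roc_curve(scores_normal=[2, 4], scores_abnormal=[1, 3])
        # J: t=1 -> 0.5, t=2 -> 0, t=3 -> 0.5, t=4 -> 0; smallest maximizer
        assert convex_point(roc) == 1

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        normal = rng.normal(4, 1.5, size=25)
        abnormal = rng.normal(2, 1.5, size=25)
        roc = roc_curve(normal, abnormal)
        best = convex_point(roc)
        scores = np.unique(np.concatenate([normal, abnormal]))
        # exact integer form of J: count pairs instead of averaging rates
        js = {
            t: int((abnormal <= t).sum()) * normal.size
            + int((normal > t).sum()) * abnormal.size
            for t in scores
        }
        jmax = max(js.values())
        assert js[best] == jmax
        assert best == min(t for t, j in js.items() if j == jmax)

    def test_cut_between_group_means_on_phantom_like_scores(self):
        rng = np.random.default_rng(12)
        normal = rng.normal(10, 1, 31)
        abnormal = rng.normal(4, 1, 31)
        cut = convex_point(roc_curve(normal, abnormal))
        assert abnormal.mean() < cut < normal.mean()

    def test_closest_topleft_rule(self):
        roc = roc_curve(scores_normal=[2, 4], scores_abnormal=[1, 3])
        assert convex_point(roc, rule="closest-topleft") in (1.0, 3.0)


class TestAUCSignificance:
    def test_null_auc_gives_p_one(self):
        assert auc_significance(0.5, 31, 31) == pytest.approx(1.0)

    def test_perfect_auc_tiny_p(self):
        assert auc_significance(1.0, 31, 31) < 1e-6

    @pytest.mark.parametrize(
        "auc,printed",
        [(0.941, 2.49e-9), (0.966, 2.97e-10), (0.930, 5.83e-9)],
    )
    def test_reproduces_published_auc_p_values(self, auc, printed):
        """Null-SE normal approximation matches the published p-values

        within the slack induced by the AUCs being printed to 3 decimals.
        """
        p = auc_significance(auc, 31, 31)
        assert math.log10(p) == pytest.approx(math.log10(printed), abs=0.06)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            auc_significance(0.9, 1, 31)


class TestTTestAndCI:
    def test_identical_summaries(self):
        s = GroupSummary(n=10, mean=1.0, sd=2.0)
        t, df, p = two_sample_t(s, s)
        assert t == 0.0 and p == pytest.approx(1.0) and df == 18

    def test_published_mean_feature_p_value(self):
        """Pooled t from the published group summaries (df = 60)."""
        a = GroupSummary(n=31, mean=0.865, sd=0.164)
        b = GroupSummary(n=31, mean=0.410, sd=0.203)
        t, df, p = two_sample_t(a, b)
        assert df == 60
        assert math.log10(p) == pytest.approx(math.log10(6.82e-14), abs=0.15)

    def test_matches_scipy_on_raw_samples(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.7, 1.3, 30)
        t, df, p = two_sample_t(a, b, variant="pooled")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        t, df, p = two_sample_t(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_equal_means_undefined(self):
        s = GroupSummary(n=5, mean=1.0, sd=0.0)
        with pytest.raises(UndefinedStatisticError):
            two_sample_t(s, s)

    def test_type_one_error_calibration(self):
        """Same-distribution groups reject at ~5% under alpha = 0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0, 1, 31)
            b = rng.normal(0, 1, 31)
            _, _, p = two_sample_t(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    @pytest.mark.parametrize(
        "mean,sd,n,low,high",
        [
            (29.419, 8.398, 31, 26.339, 32.500),  # control-group age
            (3.253, 0.456, 31, 3.086, 3.421),  # control-group SD feature
        ],
    )
    def test_ci95_published_cells(self, mean, sd, n, low, high):
        # within one unit in the last printed digit: the published bounds
        # were computed from unrounded data, ours from the printed 3-dp
        # summaries
        lo, hi = ci95(mean, sd, n)
        assert lo == pytest.approx(low, abs=1e-3)
        assert hi == pytest.approx(high, abs=1e-3)

    def test_ci95_zero_sd(self):
        assert ci95(2.0, 0.0, 10) == (2.0, 2.0)

    def test_ci95_needs_two(self):
        with pytest.raises(ValueError):
            ci95(1.0, 1.0, 1)


class TestEvaluateCohort:
    @staticmethod
    def _cohort(normal_vals, abnormal_vals):
        rows = []
        for v in normal_vals:
            rows.append({"group": "normal", "sd": v, "mean": v, "entropy": v})
        for v in abnormal_vals:
            rows.append({"group": "abnormal", "sd": v, "mean": v, "entropy": v})
        return rows

    def test_perfectly_separated_cohort(self):
        rows = self._cohort(np.linspace(5, 6, 10), np.linspace(1, 2, 10))
        report = evaluate_cohort(rows, qv="auto")
        for ev in report.per_feature.values():
            assert ev.auc == 1.0
            assert ev.kappa == 1.0
            assert ev.metrics["accuracy"] == 1.0

    def test_supplied_qvs_echoed(self):
        rows = self._cohort(np.linspace(5, 6, 5), np.linspace(1, 2, 5))
        report = evaluate_cohort(rows, qv=QVThresholds())
        assert report.per_feature["sd"].qv == 2.8
        assert report.per_feature["mean"].qv == 0.7
        assert report.per_feature["entropy"].qv == 0.3
        assert all(ev.qv_source == "supplied" for ev in report.per_feature.values())

    def test_single_group_rejected(self):
        rows = self._cohort(np.linspace(5, 6, 5), [])
        with pytest.raises(EvaluationError):
            evaluate_cohort(rows)

    def test_report_serializes(self):
        import json

        rows = self._cohort(np.linspace(5, 6, 5), np.linspace(1, 2, 5))
        report = evaluate_cohort(rows, qv="auto")
        text = json.dumps(report.to_dict())
        assert '"kappa"' in text and '"auc"' in text
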