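"""Diagnostic-statistics unit and oracle tests.

The ROC/AUC implementation is checked against an exhaustive pair-ordering
oracle, the Youden threshold against a brute-force scan, the Pearson
p-value against a permutation test, and the paired AUC comparison against
its nominal operating characteristics under simulation.
"""

import numpy as np
import pytest

from dafr import (
    ClassificationTask,
    ConfusionMetrics,
    MarginMeasurement,
    analyze_study,
    classify_margin,
    compare_auc_paired,
    confusion_at,
    make_task_labels,
    pearson,
    percent_half_up,
    roc_auc,
    youden_threshold,
)


def brute_force_auc(cases, controls):
    """Fraction of (case, control) pairs ordered correctly, ties half."""
    wins = 0.0
    for a in cases:
        for b in controls:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def make_measurements(thicknesses, saf=None, dafr=None):
    out = []
    for i, t in enumerate(thicknesses):
        out.append(MarginMeasurement(
            roi_id=f"R{i}", specimen_id="S1", true_thickness_mm=t,
            margin_class=classify_margin(t),
            saf_sbr=None if saf is None else saf[i],
            dafr_value=None if dafr is None else dafr[i]))
    return out


# twelve margins mirroring the pilot design: 1 positive, 5 close, 6 clear
TWELVE = [0.5, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 7.5, 8.0, 9.0, 10.0]


class TestMarginClasses:
    @pytest.mark.parametrize("t,expected", [
        (0.0, "positive"), (0.99, "positive"),
        (1.0, "close"), (3.0, "close"), (5.0, "close"),
        (5.01, "clear"), (10.0, "clear"),
    ])
    def test_boundaries_inclusive_at_close(self, t, expected):
        assert classify_margin(t) == expected


class TestTaskLabels:
    def test_close_task_excludes_positive(self):
        labels, included = make_task_labels(make_measurements(TWELVE),
                                            "close")
        assert len(included) == 11           # the positive margin drops out
        assert int(labels.sum()) == 5
        assert int((~labels).sum()) == 6

    def test_inadequate_task_pools_positive(self):
        labels, included = make_task_labels(make_measurements(TWELVE),
                                            "inadequate")
        assert len(included) == 12
        assert int(labels.sum()) == 6
        assert int((~labels).sum()) == 6

    def test_positive_task_controls_are_all_others(self):
        labels, included = make_task_labels(make_measurements(TWELVE),
                                            "positive")
        assert len(included) == 12
        assert int(labels.sum()) == 1

    def test_all_clear_input_raises(self):
        meas = make_measurements([6.0, 7.0, 8.0])
        with pytest.raises(ValueError, match="close"):
            make_task_labels(meas, "close")

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            ClassificationTask("bogus")


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([3, 4, 1, 2], [True, True, False, False])
        assert curve.auc == 1.0

    def test_identical_groups_give_half(self):
        curve = roc_auc([1, 2, 1, 2], [True, True, False, False])
        assert curve.auc == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_ordering(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=12), 1)   # provoke ties
        labels = np.zeros(12, bool)
        labels[:6] = True
        curve = roc_auc(scores, labels)
        expected = brute_force_auc(scores[labels], scores[~labels])
        assert curve.auc == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_direction_lower_mirrors_negated_scores(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=10)
        labels = rng.uniform(size=10) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        lo = roc_auc(scores, labels, direction="lower")
        hi = roc_auc(-scores, labels, direction="higher")
        assert lo.auc == pytest.approx(hi.auc)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=12)
        labels = np.arange(12) < 5
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_undefined_scores_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            curve = roc_auc([1.0, None, 3.0, 2.0],
                            [True, True, False, False])
        assert curve.n_cases == 1 and curve.n_controls == 2

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])


class TestYouden:
    def test_perfect_scores_hit_both_100(self):
        curve = roc_auc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        thr, cm = youden_threshold(curve)
        assert cm.sensitivity_pct == 100
        assert cm.specificity_pct == 100
        assert 3 < thr < 5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=11), 1)
        labels = np.arange(11) < 5
        curve = roc_auc(scores, labels)
        thr, cm = youden_threshold(curve, scores, labels)
        # brute force over a fine threshold grid
        best = -np.inf
        for t in np.linspace(scores.min() - 1, scores.max() + 1, 2001):
            c = confusion_at(scores, labels, t)
            j = c.sensitivity + c.specificity - 1.0
            best = max(best, j)
        j_impl = cm.sensitivity + cm.specificity - 1.0
        assert j_impl == pytest.approx(best, abs=1e-12)

    def test_spec_worked_example_scan(self):
        scores = np.array([2, 3, 4, 5, 6, 1, 1, 1, 5, 6, 7], float)
        labels = np.arange(11) < 5
        curve = roc_auc(scores, labels)
        thr, cm = youden_threshold(curve, scores, labels)
        js = []
        for t in np.linspace(-1, 9, 5001):
            c = confusion_at(scores, labels, t)
            js.append(c.sensitivity + c.specificity - 1.0)
        assert cm.sensitivity + cm.specificity - 1.0 == pytest.approx(
            max(js), abs=1e-12)

    def test_single_case_single_control(self):
        curve = roc_auc([2.0, 1.0], [True, False])
        thr, cm = youden_threshold(curve)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0
        assert thr == pytest.approx(1.5)


class TestConfusion:
    def test_saf_worked_example(self):
        # 5/5 close margins detected, half of 6 clear margins misclassified
        cm = ConfusionMetrics(threshold=1.3, tp=5, fp=3, tn=3, fn=0)
        assert cm.sensitivity_pct == 100
        assert cm.specificity_pct == 50
        assert cm.ppv_pct == 63          # half-up from 62.5
        assert cm.npv_pct == 100

    def test_dafr_worked_example(self):
        cm = ConfusionMetrics(threshold=0.63, tp=5, fp=0, tn=6, fn=0)
        assert (cm.sensitivity_pct, cm.specificity_pct, cm.ppv_pct,
                cm.npv_pct) == (100, 100, 100, 100)

    def test_zero_denominator_is_undefined_not_zero(self):
        cm = ConfusionMetrics(threshold=0.0, tp=0, fp=0, tn=3, fn=0)
        assert cm.ppv is None and cm.ppv_pct is None
        assert cm.sensitivity is None

    def test_counts_from_scores(self):
        cm = confusion_at([2.0, 0.5, 1.8, 0.9], [True, True, False, False],
                          1.0, "higher")
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)

    @pytest.mark.parametrize("p,expected", [
        (0.625, 63), (0.5, 50), (0.005, 1), (0.994, 99), (1.0, 100),
        (0.615, 62), (None, None),
    ])
    def test_percent_half_up(self, p, expected):
        assert percent_half_up(p) == expected


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x)
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_flagged_undefined(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert "constant" in res.note

    def test_p_value_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        res = pearson(x, y)
        n_perm = 200_000
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        for chunk in range(20):
            perms = rng.permuted(
                np.tile(y, (n_perm // 20, 1)), axis=1)
            xc = x - x.mean()
            yc = perms - perms.mean(axis=1, keepdims=True)
            rs = (yc @ xc) / np.sqrt((xc @ xc) * (yc ** 2).sum(axis=1))
            count += int((np.abs(rs) >= r_obs - 1e-12).sum())
        p_perm = count / n_perm
        # permutation MC s.e. plus the small-n discrepancy between the
        # permutation and t reference distributions
        assert res.p_value == pytest.approx(p_perm, abs=0.015)


class TestPairedAUC:
    def test_identical_markers_null(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=20)
        labels = np.arange(20) < 10
        res = compare_auc_paired(s, s, labels)
        assert res.difference == 0.0
        assert res.p_value == 1.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_invariants(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=24)
        b = rng.normal(size=24)
        labels = np.arange(24) < 12
        res = compare_auc_paired(a, b, labels)
        assert res.difference == pytest.approx(res.auc_a - res.auc_b)
        assert res.ci_low <= res.difference <= res.ci_high

    def test_power_when_one_marker_separates(self):
        # marker A perfectly separates; marker B is pure noise
        rng = np.random.default_rng(7)
        rejections = 0
        for rep in range(200):
            labels = np.arange(200) < 100
            a = labels + 0.01 * rng.normal(size=200)
            b = rng.normal(size=200)
            res = compare_auc_paired(a, b, labels)
            rejections += res.p_value < 0.05
        assert rejections / 200 > 0.95

    def test_type_one_error_near_nominal(self):
        # both markers pure noise: rejection rate ~ alpha
        rng = np.random.default_rng(11)
        n_rep = 1000
        rejections = 0
        for rep in range(n_rep):
            labels = np.arange(40) < 20
            a = rng.normal(size=40)
            b = rng.normal(size=40)
            res = compare_auc_paired(a, b, labels)
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 2 * se + 0.01

    def test_matches_sklearn_auc_values(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        labels = np.arange(30) < 15
        res = compare_auc_paired(a, b, labels)
        assert res.auc_a == pytest.approx(roc_auc_score(labels, a))
        assert res.auc_b == pytest.approx(roc_auc_score(labels, b))


class TestAnalyzeStudy:
    def _measurements(self):
        rng = np.random.default_rng(1)
        saf = [8.0 - 0.5 * t + 0.3 * rng.normal() for t in TWELVE]
        dafr = [104 - 1.5 * t for t in TWELVE]  # falls with depth, as
        # the forward model's wide/narrow ratio does
        return make_measurements(TWELVE, saf=saf, dafr=dafr)

    def test_report_cardinality(self):
        report = analyze_study(self._measurements())
        tasks = report["tasks"]
        n_roc = sum(1 for t in tasks.values()
                    for m in t.get("markers", {}).values() if "auc" in m)
        assert n_roc == 6                       # 2 markers x 3 tasks
        assert len(report["correlations"]) == 2
        assert len(report["auc_comparisons"]) == 3

    def test_separating_dafr_gives_auc_one(self):
        report = analyze_study(self._measurements())
        assert report["tasks"]["close"]["markers"]["dafr"]["auc"] == 1.0

    def test_deterministic_rerun(self):
        m = self._measurements()
        assert analyze_study(m) == analyze_study(m)

    def test_missing_class_task_skipped(self):
        meas = make_measurements([2.0, 3.0, 6.0, 7.0],
                                 saf=[3, 2.5, 1, 0.9],
                                 dafr=[104, 103, 96, 95])
        report = analyze_study(meas)
        assert "skipped" in report["tasks"]["positive"]
        assert "auc" in report["tasks"]["close"]["markers"]["dafr"]
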