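"""Evaluation statistics: PR curves, thresholds, bootstrap, agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgdx.evaluate import (
    bootstrap_scores,
    class_scores,
    cohen_kappa,
    evaluate,
    macro_f1,
    mcnemar_test,
    micro_average_precision,
    pr_curve,
    select_run_above_median,
    select_threshold_max_f1,
)


def brute_force_best_f1(scores, labels):
    """Oracle: exhaustive search over every cut-point, highest-threshold tie-break."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = (-1.0, None)
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if (f1, thr) >= best:
            best = (f1, thr)
    return best


class TestPRCurve:
    def test_hand_example(self):
        recall, precision, thr = pr_curve([0.9, 0.8, 0.3], [1, 0, 1])
        at_08 = np.flatnonzero(thr == 0.8)[0]
        assert precision[at_08] == pytest.approx(0.5)
        assert recall[at_08] == pytest.approx(0.5)

    def test_perfect_separation_has_unit_precision(self, rng):
        # At every achievable recall level the best operating point has
        # precision 1 (thresholds below the separating gap trade nothing).
        y = np.r_[np.ones(10), np.zeros(30)].astype(bool)
        s = np.r_[0.6 + 0.4 * rng.random(10), 0.4 * rng.random(30)]
        recall, precision, _ = pr_curve(s, y)
        for r in np.unique(recall):
            assert precision[recall == r].max() == 1.0

    def test_lowest_threshold_reaches_full_recall(self, rng):
        y = rng.random(1000) < 0.2
        s = rng.random(1000)
        recall, _, _ = pr_curve(s, y)
        assert recall[0] == 1.0  # ascending threshold order
        assert np.all(np.diff(recall) <= 0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.1, 0.2], [0, 0])


class TestThresholdSelection:
    def test_perfect_separation_reaches_f1_one(self, rng):
        y = np.r_[np.ones(5), np.zeros(15)].astype(bool)
        s = np.r_[0.8 + 0.2 * rng.random(5), 0.5 * rng.random(15)]
        thr = select_threshold_max_f1(s, y)
        assert macro_f1(s[:, None], y[:, None], [thr]) == 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        s = np.round(rng.random(n), 2)  # force score ties
        y = rng.random(n) < 0.4
        if not y.any():
            y[0] = True
        thr = select_threshold_max_f1(s, y)
        best_f1, best_thr = brute_force_best_f1(s, y)
        got = class_scores(s[:, None], y[:, None], [thr])["class0"]["f1"]
        assert got == pytest.approx(best_f1)
        assert thr == pytest.approx(best_thr)

    def test_duplicating_a_record_keeps_optimum(self, rng):
        s = rng.random(20)
        y = rng.random(20) < 0.5
        if not y.any():
            y[0] = True
        f1_a, _ = brute_force_best_f1(s, y)
        s2, y2 = np.r_[s, s[3]], np.r_[y, y[3]]
        thr = select_threshold_max_f1(s2, y2)
        f1_b = class_scores(s2[:, None], y2[:, None], [thr])["class0"]["f1"]
        assert f1_b == pytest.approx(brute_force_best_f1(s2, y2)[0])


class TestClassScores:
    def test_direct_formula(self):
        s = np.r_[np.full(9, 0.9), [0.9], np.full(1, 0.1), np.full(89, 0.1)][:, None]
        y = np.r_[np.ones(9), [0.0], np.ones(1), np.zeros(89)].astype(bool)[:, None]
        out = class_scores(s, y, [0.5])["class0"]
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (9, 1, 1, 89)
        assert out["precision"] == pytest.approx(0.9)
        assert out["recall"] == pytest.approx(0.9)
        assert out["f1"] == pytest.approx(0.9)

    def test_metric_closure_from_counts(self, rng):
        s = rng.random((50, 6))
        y = rng.random((50, 6)) < 0.3
        out = class_scores(s, y, [0.5] * 6)
        for v in out.values():
            tp, fp, fn, tn = v["tp"], v["fp"], v["fn"], v["tn"]
            if tp + fp:
                assert v["precision"] == tp / (tp + fp)
            if tp + fn:
                assert v["recall"] == tp / (tp + fn)
            assert v["specificity"] == tn / (tn + fp)

    def test_undefined_ratios_are_missing_not_zero(self):
        s = np.zeros((5, 1))
        y = np.array([1, 1, 0, 0, 0], bool)[:, None]
        out = class_scores(s, y, [0.5])["class0"]
        assert out["recall"] == 0.0
        assert np.isnan(out["precision"])

    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0], bool)[:, None]
        s = y.astype(float)
        out = class_scores(s, y, [0.5])["class0"]
        assert (out["precision"], out["recall"], out["specificity"], out["f1"]) == (1, 1, 1, 1)


class TestMicroAP:
    def test_perfect_separation_is_one(self):
        s = np.array([[0.9], [0.8], [0.2], [0.1]])
        y = np.array([[1], [1], [0], [0]], bool)
        assert micro_average_precision(s, y) == 1.0

    def test_rank_by_rank_oracle(self):
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])[:, None]
        y = np.array([1, 0, 1, 0, 0, 1], bool)[:, None]
        # positives at ranks 1, 3, 6 -> (1/1 + 2/3 + 3/6) / 3
        assert micro_average_precision(s, y) == pytest.approx((1 + 2 / 3 + 0.5) / 3)

    def test_sklearn_cross_check_and_permutation(self, rng):
        from sklearn.metrics import average_precision_score

        s = rng.random((40, 6))
        y = rng.random((40, 6)) < 0.3
        ours = micro_average_precision(s, y)
        theirs = average_precision_score(y.ravel().astype(int), s.ravel())
        assert ours == pytest.approx(theirs, rel=1e-12)
        perm = rng.permutation(6)
        assert micro_average_precision(s[:, perm], y[:, perm]) == pytest.approx(ours)


class TestBootstrap:
    def test_degenerate_data_gives_point_distribution(self):
        y = np.array([[1], [1], [0], [0]] * 10, bool)
        s = y.astype(float)
        out = bootstrap_scores(s, y, [0.5], n_resamples=50, seed=0)
        f1 = out["class0"]["f1"]
        assert f1["lo"] == f1["hi"] == f1["point"] == 1.0

    def test_interval_contains_point_estimate(self, rng):
        s = rng.random((200, 6))
        y = (s + rng.normal(0, 0.3, s.shape)) > 0.5
        out = bootstrap_scores(s, y, [0.5] * 6, n_resamples=200, seed=1)
        for cls in out.values():
            for m in cls.values():
                if np.isfinite(m["point"]):
                    assert m["lo"] - 1e-9 <= m["point"] <= m["hi"] + 1e-9

    def test_seeded_reproducibility_bitwise(self, rng):
        s = rng.random((50, 6))
        y = rng.random((50, 6)) < 0.4
        a = bootstrap_scores(s, y, [0.5] * 6, n_resamples=100, seed=9)
        b = bootstrap_scores(s, y, [0.5] * 6, n_resamples=100, seed=9)
        for cls in a:
            for m in a[cls]:
                assert np.array_equal(
                    a[cls][m]["distribution"], b[cls][m]["distribution"], equal_nan=True
                )


class TestAgreement:
    def test_mcnemar_symmetric_discordance_is_zero(self):
        a = np.r_[np.ones(5), np.zeros(5), np.zeros(10)].astype(bool)
        b = np.r_[np.zeros(5), np.ones(5), np.zeros(10)].astype(bool)
        stat, _ = mcnemar_test(a, b, exact="never")
        assert stat == 0.0

    def test_mcnemar_direct_formula(self):
        a = np.r_[np.ones(10), np.zeros(2), np.zeros(40)].astype(bool)
        b = np.r_[np.zeros(10), np.ones(2), np.zeros(40)].astype(bool)
        stat, _ = mcnemar_test(a, b, exact="never")
        assert stat == pytest.approx((10 - 2) ** 2 / 12)

    def test_mcnemar_exact_closed_form(self):
        a = np.r_[np.ones(3), np.zeros(5)].astype(bool)
        b = np.zeros(8, bool)
        stat, p = mcnemar_test(a, b)
        assert p == pytest.approx(2 * 0.5**3)

    def test_mcnemar_statsmodels_cross_check(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm

        a = np.r_[np.ones(7), np.zeros(3), np.zeros(30)].astype(bool)
        b = np.r_[np.zeros(7), np.ones(3), np.zeros(30)].astype(bool)
        _, p = mcnemar_test(a, b)
        both_right = int((~a & ~b).sum())
        ref = sm([[both_right, 7], [3, 0]], exact=True).pvalue
        assert p == pytest.approx(ref)

    def test_mcnemar_no_discordance(self):
        a = np.zeros(10, bool)
        assert mcnemar_test(a, a) == (0.0, 1.0)

    def test_kappa_identity_and_negation(self):
        a = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        assert cohen_kappa(a, a) == 1.0
        assert cohen_kappa(a, ~a) == -1.0

    def test_kappa_direct_table(self):
        a = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        b = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)].astype(bool)
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_kappa_sklearn_cross_check(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.random(100) < 0.4
        b = rng.random(100) < 0.4
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_kappa_bounds_property(self, rng):
        for _ in range(20):
            a = rng.random(30) < rng.random()
            b = rng.random(30) < rng.random()
            assert -1.0 - 1e-12 <= cohen_kappa(a, b) <= 1.0 + 1e-12


class TestModelSelection:
    def test_run_immediately_above_median(self):
        maps = [0.946, 0.950, 0.951, 0.960, 0.961, 0.948, 0.949, 0.952, 0.955, 0.958]
        idx = select_run_above_median(maps)
        med = np.median(maps)
        above = [v for v in maps if v > med]
        assert maps[idx] == min(above)


class TestReport:
    def test_f1_at_selected_threshold_dominates(self, rng):
        s = rng.random((100, 6))
        y = (s + rng.normal(0, 0.4, s.shape)) > 0.6
        y[0] = True  # ensure positives everywhere
        rep = evaluate(s, y, n_bootstrap=10, seed=0)
        for j, (name, entry) in enumerate(rep["classes"].items()):
            for other in np.linspace(0.05, 0.95, 10):
                alt = class_scores(s, y, [other if k == j else entry["threshold"]
                                          for k in range(6)])[name]["f1"]
                if np.isfinite(alt):
                    assert alt <= entry["f1"] + 1e-12
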