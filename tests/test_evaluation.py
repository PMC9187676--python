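"""Diagnostic statistics: confusion metrics, exact CIs, ROC/DeLong, CV."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import slidestream as ss
from slidestream.evaluation import EvaluationError, _delong_components


def _table(scores, labels, ids=None):
    n = len(scores)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    return ss.ScoreTable(ids, np.zeros(n), np.asarray(scores, float), np.asarray(labels))


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,sens,spec,mcc",
        [
            ((263, 12, 32, 849), 0.8915, 0.9861, 0.8986),  # model, operating point 0.4
            ((289, 2, 6, 859), 0.9797, 0.9977, 0.9818),  # expert pathologist
            ((286, 11, 9, 850), 0.9695, 0.9872, 0.9546),
            ((5217, 391, 82, 9544), 0.9845, 0.9606, 0.9334),
        ],
    )
    def test_published_confusion_tables_reproduce(self, counts, sens, spec, mcc):
        m = ss.confusion_metrics(ss.ConfusionMatrix(*counts))
        assert round(m["sensitivity"], 4) == sens
        assert round(m["specificity"], 4) == spec
        assert round(m["mcc"], 4) == mcc

    def test_perfect_classifier(self):
        m = ss.confusion_metrics(ss.ConfusionMatrix(10, 0, 0, 20))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "mcc"))

    def test_undefined_marker_and_mcc_zero_convention(self):
        m = ss.confusion_metrics(ss.ConfusionMatrix(0, 0, 0, 5))
        assert m["sensitivity"] is None and m["ppv"] is None
        assert m["mcc"] == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(EvaluationError):
            ss.ConfusionMatrix(0, 0, 0, 0)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_mcc_symmetry_and_range(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m1 = ss.confusion_metrics(ss.ConfusionMatrix(tp, fp, fn, tn))["mcc"]
        m2 = ss.confusion_metrics(ss.ConfusionMatrix(tn, fn, fp, tp))["mcc"]
        m3 = ss.confusion_metrics(ss.ConfusionMatrix(fn, tn, tp, fp))["mcc"]
        assert -1.0 - 1e-12 <= m1 <= 1.0 + 1e-12
        assert np.isclose(m1, m2)  # swap tp<->tn, fp<->fn
        assert np.isclose(m1, -m3) or (m1 == 0 and m3 == 0)  # label inversion


class TestClopperPearson:
    def test_published_interval(self):
        lo, hi = ss.clopper_pearson(263, 295, 0.95)
        assert round(lo, 4) == 0.8503
        assert round(hi, 4) == 0.9246

    def test_boundary_cases(self):
        assert ss.clopper_pearson(0, 10)[0] == 0.0
        assert ss.clopper_pearson(10, 10)[1] == 1.0

    def test_interval_contains_point_estimate(self):
        for x, n in [(1, 10), (5, 10), (50, 200), (199, 200)]:
            lo, hi = ss.clopper_pearson(x, n)
            assert lo <= x / n <= hi

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = []
        for n in (20, 80, 320):
            lo, hi = ss.clopper_pearson(n // 2, n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_definition_matches_binomial_tail(self):
        # exactness oracle: at the lower bound, P(X >= x | p=lo) = alpha/2
        from scipy.stats import binom

        x, n = 263, 295
        lo, hi = ss.clopper_pearson(x, n, 0.95)
        assert np.isclose(binom.sf(x - 1, n, lo), 0.025, atol=1e-10)
        assert np.isclose(binom.cdf(x, n, hi), 0.025, atol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(EvaluationError):
            ss.clopper_pearson(5, 3)


class TestRocAuc:
    def test_perfect_separation(self):
        t = _table([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ss.roc_auc(t) == 1.0

    def test_all_scores_equal_gives_half(self):
        t = _table([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert ss.roc_auc(t) == 0.5

    def test_matches_brute_force_pair_enumeration(self, rng):
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 6)
        labels = [1, 1, 0, 0, 1, 0]
        t = _table(scores, labels)
        pos = scores[np.array(labels) == 1]
        neg = scores[np.array(labels) == 0]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert np.isclose(ss.roc_auc(t), brute)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert np.isclose(ss.roc_auc(_table(scores, labels)), roc_auc_score(labels, scores))

    @given(st.integers(0, 100))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(20)
        labels = np.r_[np.ones(8, int), np.zeros(12, int)]
        a1 = ss.roc_auc(_table(scores, labels))
        a2 = ss.roc_auc(_table(np.exp(3 * scores), labels))
        assert np.isclose(a1, a2)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            ss.roc_auc(_table([0.1, 0.2], [1, 1]))


class TestDeLong:
    def test_same_table_gives_zero_delta_p_one(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        t = _table(scores, labels)
        out = ss.delong(t, t)
        assert out["delta_auc"] == 0.0
        assert out["p_value"] == 1.0

    def test_perfect_separation_degenerate_ci(self):
        t = _table([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        out = ss.delong(t)
        assert out["auc"] == 1.0
        assert out["variance"] == 0.0
        assert out["ci"] == (1.0, 1.0)

    def test_variance_close_to_bootstrap_oracle(self, rng):
        scores = rng.random(20)
        labels = np.r_[np.ones(8, int), np.zeros(12, int)]
        t = _table(scores, labels)
        out = ss.delong(t)
        # bootstrap oracle (n = 10000 stratified resamples)
        pos, neg = scores[:8], scores[8:]
        aucs = []
        for _ in range(10000):
            bp = rng.choice(pos, 8)
            bn = rng.choice(neg, 12)
            aucs.append(np.mean([(p > q) + 0.5 * (p == q) for p in bp for q in bn]))
        boot_var = np.var(aucs, ddof=1)
        assert abs(out["variance"] - boot_var) / boot_var < 0.15

    def test_component_means_equal_auc(self, rng):
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        auc, v10, v01 = _delong_components(scores, labels)
        assert np.isclose(v10.mean(), auc) and np.isclose(v01.mean(), auc)
        assert np.isclose(auc, ss.roc_auc(_table(scores, labels)))

    def test_unpaired_inputs_rejected(self, rng):
        t1 = _table(rng.random(10), [1, 0] * 5, ids=np.arange(10))
        t2 = _table(rng.random(10), [1, 0] * 5, ids=np.arange(10) + 100)
        with pytest.raises(EvaluationError):
            ss.delong(t1, t2)


class TestAggregationAndThresholds:
    def test_slide_score_is_maximum(self):
        assert ss.slide_score([0.1, 0.9, 0.3]) == 0.9
        assert ss.slide_score([0.42]) == 0.42
        assert ss.slide_score([0.0, 0.0]) == 0.0
        with pytest.raises(EvaluationError):
            ss.slide_score([])

    def test_classify_inclusive_boundary(self):
        t = _table([0.4, 0.39999], [1, 0])
        assert list(ss.classify(t, 0.4)) == [1, 0]

    def test_screening_threshold_never_less_sensitive(self, rng):
        t = _table(rng.random(50), rng.integers(0, 2, 50))
        assert ss.classify(t, 0.15).sum() >= ss.classify(t, 0.4).sum()

    def test_aggregate_then_threshold_equals_threshold_then_any(self, rng):
        for _ in range(20):
            scores = rng.random(rng.integers(1, 6))
            thr = rng.random()
            assert (ss.slide_score(scores) >= thr) == bool(np.any(scores >= thr))

    def test_pick_threshold_finds_clean_separation(self):
        t = _table([0.9, 0.8, 0.45, 0.35, 0.2, 0.1], [1, 1, 1, 0, 0, 0])
        grid = np.round(np.linspace(0.05, 0.95, 19), 2)
        assert ss.pick_threshold_mcc(t, grid) == 0.4

    def test_pick_threshold_single_class_warns_and_falls_back(self):
        t = _table([0.5, 0.6], [1, 1])
        with pytest.warns(UserWarning):
            assert ss.pick_threshold_mcc(t, [0.2, 0.5, 0.7]) == 0.2

    def test_pick_threshold_single_value_grid(self):
        t = _table([0.9, 0.1], [1, 0])
        assert ss.pick_threshold_mcc(t, [0.33]) == 0.33


class TestCountCV:
    def test_equal_counts_give_zero(self):
        assert ss.count_cv([4, 4, 4]) == 0.0
        assert ss.count_cv([0, 0]) == 0.0  # all-zero convention

    def test_hand_computed_value(self):
        # sd = sqrt(1/3), mean = 4/3 -> 0.4330
        assert round(ss.count_cv([1, 1, 2]), 4) == 0.4330

    def test_unbiased_variance_used(self):
        counts = [2, 4, 6, 8]
        expect = np.std(counts, ddof=1) / np.mean(counts)
        assert np.isclose(ss.count_cv(counts), expect)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(EvaluationError):
            ss.count_cv([3])


def test_score_table_csv_roundtrip(tmp_path, rng):
    t = _table(rng.random(10), rng.integers(0, 2, 10))
    p = tmp_path / "scores.csv"
    t.to_csv(p)
    t2 = ss.ScoreTable.from_csv(p)
    assert np.allclose(t.scores, t2.scores)
    assert np.array_equal(t.labels, t2.labels)
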