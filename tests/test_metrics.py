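"""ROC/AUC definitions, confusion counts, and survival statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import combosearch as cs
from combosearch.errors import DegenerateCohortError, DegenerateGroupError
from combosearch.metrics import as_percent


def _random_instance(rng, n_max=50, tie_prob=0.3):
    n = rng.integers(4, n_max + 1)
    y = rng.integers(0, 2, size=n)
    y[:2] = [0, 1]
    if rng.random() < tie_prob:
        scores = rng.integers(-3, 4, size=n).astype(float)  # many ties
    else:
        scores = rng.normal(size=n)
    return scores, y


class TestConfusion:
    def test_basic_tally(self):
        c = cs.confusion_at_threshold([2, 1, -1, -2], [1, 1, 0, 0], 0.0)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 0, 2, 0)

    def test_threshold_above_all_scores(self):
        c = cs.confusion_at_threshold([2, 1, -1, -2], [1, 1, 0, 0], 10.0)
        assert c.tp == 0 and c.tn == 2 and c.fn == 2 and c.fp == 0

    def test_strict_inequality_at_threshold(self):
        c = cs.confusion_at_threshold([0.0, 1.0], [1, 0], 0.0)
        assert c.tp == 0 and c.fn == 1  # score == threshold predicts negative

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores, y = _random_instance(rng)
            thr = float(rng.normal())
            c = cs.confusion_at_threshold(scores, y, thr)
            tp = sum(1 for s, l in zip(scores, y) if s > thr and l == 1)
            fp = sum(1 for s, l in zip(scores, y) if s > thr and l == 0)
            fn = sum(1 for s, l in zip(scores, y) if s <= thr and l == 1)
            tn = sum(1 for s, l in zip(scores, y) if s <= thr and l == 0)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            cs.confusion_at_threshold([1.0, 2.0], [1, 1], 0.0)


class TestSensitivitySpecificity:
    def test_fractions_and_percent_rounding(self):
        sens, spec = cs.sensitivity_specificity(
            cs.ConfusionCounts(tp=9, fp=3, tn=5, fn=1)
        )
        assert sens == pytest.approx(0.9)
        assert as_percent(sens) == 90.0
        # 27 of 33 recurrences caught -> 81.8% at one decimal
        sens2, _ = cs.sensitivity_specificity(cs.ConfusionCounts(27, 0, 1, 6))
        assert as_percent(sens2) == 81.8

    def test_zero_correct_predictions(self):
        sens, spec = cs.sensitivity_specificity(cs.ConfusionCounts(0, 4, 0, 5))
        assert sens == 0.0 and spec == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(DegenerateCohortError):
            cs.sensitivity_specificity(cs.ConfusionCounts(0, 3, 2, 0))


class TestRocCurve:
    def test_perfect_and_inverted_separation(self):
        perfect = cs.roc_curve([3.0, 2.0, -1.0, -2.0], [1, 1, 0, 0])
        assert any(f == 0.0 and t == 1.0 for f, t in zip(perfect.fpr, perfect.tpr))
        inverted = cs.roc_curve([-3.0, -2.0, 1.0, 2.0], [1, 1, 0, 0])
        assert any(f == 1.0 and t == 0.0 for f, t in zip(inverted.fpr, inverted.tpr))

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores, y = _random_instance(rng)
            roc = cs.roc_curve(scores, y)
            assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
            assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
            assert (np.diff(roc.fpr) >= 0).all()
            assert (np.diff(roc.tpr) >= 0).all()
            assert roc.thresholds[0] == np.inf

    def test_vertices_match_threshold_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores, y = _random_instance(rng)
            roc = cs.roc_curve(scores, y)
            n_pos, n_neg = int(np.sum(y)), int(np.sum(1 - y))
            expected = [(0.0, 0.0)]
            for s in sorted(set(scores), reverse=True):
                pred = scores >= s  # threshold just below s
                fpr = np.sum(pred & (y == 0)) / n_neg
                tpr = np.sum(pred & (y == 1)) / n_pos
                expected.append((fpr, tpr))
            got = list(zip(roc.fpr, roc.tpr))
            assert got == pytest.approx(expected)


class TestAuc:
    def test_analytic_anchors(self):
        assert cs.auc([3.0, 2.0, -1.0, -2.0], [1, 1, 0, 0]) == 1.0
        assert cs.auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        n = 4000
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        assert cs.auc(rng.normal(size=n), y) == pytest.approx(0.5, abs=0.03)

    @given(st.integers(0, 10_000))
    def test_equals_mann_whitney_u(self, seed):
        """Oracle equivalence: AUC == U / (n_pos * n_neg), ties included."""
        rng = np.random.default_rng(seed)
        scores, y = _random_instance(rng)
        u = sps.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        expect = u / (np.sum(y) * np.sum(1 - y))
        assert cs.auc(scores, y) == pytest.approx(expect, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores, y = _random_instance(rng)
        a = cs.auc(scores, y)
        assert cs.auc(np.exp(scores) * 3 + 1, y) == pytest.approx(a, abs=1e-12)
        assert cs.auc(scores - 100.0, y) == pytest.approx(a, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_negated_scores_complement(self, seed):
        rng = np.random.default_rng(seed)
        scores, y = _random_instance(rng, tie_prob=0.0)
        scores = scores + np.arange(len(scores)) * 1e-9  # tie-free
        assert cs.auc(scores, y) + cs.auc(-scores, y) == pytest.approx(1.0, abs=1e-12)

    def test_threshold_sweep_moves_sens_spec_oppositely(self):
        rng = np.random.default_rng(5)
        scores, y = _random_instance(rng, tie_prob=0.0)
        sens, spec = [], []
        for thr in np.linspace(scores.min() - 1, scores.max() + 1, 25):
            c = cs.confusion_at_threshold(scores, y, thr)
            sens.append(c.tp / c.n_positives)
            spec.append(c.tn / c.n_negatives)
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()


def _km_oracle(times, events):
    """Independent product-limit estimator by direct counting."""
    s = 1.0
    out = {}
    for t in sorted(set(times[events])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        curves = cs.kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0], ["a", "a", "a"])
        assert (curves["a"]["survival"] == 1.0).all()

    def test_all_events_closed_form(self):
        n = 5
        curves = cs.kaplan_meier(
            np.arange(1.0, n + 1), np.ones(n, dtype=bool), ["g"] * n
        )
        surv = curves["g"]["survival"].to_numpy()
        expect = np.array([1.0] + [(n - i) / n for i in range(1, n + 1)])
        assert np.allclose(surv, expect)

    def test_matches_product_limit_oracle(self):
        rng = np.random.default_rng(6)
        times = rng.uniform(0.5, 10, size=60)
        events = rng.random(60) < 0.6
        curves = cs.kaplan_meier(times, events, ["x"] * 60)
        df = curves["x"]
        oracle = _km_oracle(times, events)
        lookup = dict(zip(df["time"], df["survival"]))
        for t, s in oracle.items():
            assert lookup[t] == pytest.approx(s, abs=1e-12)

    def test_empty_group_impossible_nonempty_required(self):
        with pytest.raises(DegenerateGroupError):
            cs.logrank_test([1.0, 2.0], [1, 0], ["a", "a"])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 0, 1, 1, 0, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        stat, p = cs.logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(7)
        times = rng.uniform(0.5, 10, size=40)
        events = rng.random(40) < 0.7
        groups = np.where(rng.random(40) < 0.5, "a", "b")
        s1, p1 = cs.logrank_test(times, events, groups)
        swapped = np.where(groups == "a", "b", "a")
        s2, p2 = cs.logrank_test(times, events, swapped)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_separated_groups_agree_with_permutation_reference(self):
        rng = np.random.default_rng(8)
        n = 30
        times = np.r_[rng.exponential(2.0, n), rng.exponential(8.0, n)]
        events = np.ones(2 * n, dtype=bool)
        groups = np.array(["hi"] * n + ["lo"] * n)
        stat, p = cs.logrank_test(times, events, groups)
        assert p < 0.01
        # permutation reference: observed statistic should be extreme
        exceed = 0
        reps = 200
        for _ in range(reps):
            s, _ = cs.logrank_test(times, events, rng.permutation(groups))
            exceed += s >= stat
        assert exceed / reps < 0.02
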