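import itertools

import numpy as np
import pytest
from scipy import stats

from polarcall.evaluate import (
    EvalConfig,
    aggregate_raters,
    bootstrap_ci,
    confusion_metrics,
    evaluate_frames,
    pearson_corr,
    roc_auc,
    two_proportion_ztest,
    wilcoxon_signed_rank,
)


def brute_force_auc(scores, truth):
    """Independent oracle: pairwise concordance with ties counted 1/2."""
    scores, truth = np.asarray(scores), np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_wilcoxon(diffs):
    """Independent oracle: enumerate every sign assignment explicitly."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        if min(wp, ranks.sum() - wp) <= w_obs + 1e-12:
            count += 1
        total += 1
    return w_obs, count / total


class TestConfusionMetrics:
    def test_printed_accuracy(self):
        truth = np.zeros(583, dtype=int)
        pred = np.zeros(583, dtype=int)
        pred[:86] = 1  # 86 mismatches -> 497 correct
        rep = confusion_metrics(pred, truth)
        assert rep.accuracy * 100 == pytest.approx(85.2, abs=0.05)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 1, 0, 1])
        rep = confusion_metrics(truth, truth)
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == (1.0, 1.0, 1.0)

    def test_all_positive_predictions(self):
        rep = confusion_metrics([1, 1, 1, 1], [0, 1, 0, 1])
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0

    def test_metric_consistency_identity(self, rng):
        pred = rng.integers(0, 2, 200)
        true = rng.integers(0, 2, 200)
        rep = confusion_metrics(pred, true)
        P, N = rep.tp + rep.fn, rep.tn + rep.fp
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * P + rep.specificity * N) / (P + N)
        )

    def test_undefined_ratio_warns(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            rep = confusion_metrics([0, 0], [0, 0])
        assert np.isnan(rep.sensitivity)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_derived_fixture(self):
        _, auc = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 200))
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            _, auc = roc_auc(scores, truth)
            assert auc == pytest.approx(brute_force_auc(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBootstrapCi:
    def test_constant_vector_degenerate_interval(self):
        assert bootstrap_ci(np.full(20, 3.5)) == (3.5, 3.5)

    def test_matches_printed_accuracy_interval(self):
        outcomes = np.zeros(583)
        outcomes[:497] = 1
        lo, hi = bootstrap_ci(outcomes, EvalConfig(n_bootstrap=1000, seed=7))
        assert lo * 100 == pytest.approx(82.2, abs=0.5)
        assert hi * 100 == pytest.approx(88.2, abs=0.5)

    def test_interval_widens_with_level(self, rng):
        x = rng.normal(size=60)
        lo90, hi90 = bootstrap_ci(x, EvalConfig(ci_level=90, seed=3))
        lo99, hi99 = bootstrap_ci(x, EvalConfig(ci_level=99, seed=3))
        assert lo99 <= lo90 and hi99 >= hi90

    def test_converges_to_normal_interval(self):
        """Percentile bootstrap of a binary mean approaches the normal
        approximation for large B."""
        outcomes = np.zeros(583)
        outcomes[:497] = 1
        lo, hi = bootstrap_ci(outcomes, EvalConfig(n_bootstrap=10_000, seed=5))
        p = outcomes.mean()
        se = np.sqrt(p * (1 - p) / outcomes.size)
        assert lo == pytest.approx(p - 1.959964 * se, abs=0.01)
        assert hi == pytest.approx(p + 1.959964 * se, abs=0.01)

    def test_deterministic_given_seed(self, rng):
        x = rng.random(50)
        assert bootstrap_ci(x, EvalConfig(seed=9)) == bootstrap_ci(x, EvalConfig(seed=9))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestTwoProportionZtest:
    def test_hand_computed_fixture(self):
        z, p = two_proportion_ztest(80, 100, 60, 100)
        assert z == pytest.approx(3.086, abs=1e-3)
        assert p == pytest.approx(0.00203, abs=1e-4)

    def test_equal_proportions(self):
        z, p = two_proportion_ztest(30, 60, 25, 50)
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetric_in_groups(self):
        z1, p1 = two_proportion_ztest(80, 100, 60, 100)
        z2, p2 = two_proportion_ztest(60, 100, 80, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_flagged(self):
        with pytest.warns(UserWarning):
            z, p = two_proportion_ztest(0, 10, 0, 10)
        assert np.isnan(z)


class TestWilcoxon:
    def test_all_positive_n6(self):
        w, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert w == 0.0
        assert p == pytest.approx(2 / 64)

    def test_antisymmetric_pairs(self):
        _, p = wilcoxon_signed_rank([3, -3, 5, -5])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(6):
            n = int(rng.integers(3, 11))
            d = np.round(rng.normal(size=n) * 3, 1)  # rounding makes ties
            if (d == 0).all():
                continue
            w, p = wilcoxon_signed_rank(d)
            w_ref, p_ref = brute_force_wilcoxon(d)
            assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        d = np.array([1.1, -2.3, 3.7, 4.2, -5.9, 6.1, 7.8, -8.4])
        w, p = wilcoxon_signed_rank(d)
        res = stats.wilcoxon(d, mode="exact")
        assert w == res.statistic
        assert p == pytest.approx(res.pvalue)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(1.0, 1.0, 40)
        w, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=False, mode="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestPearson:
    def test_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x, y = rng.random(30), rng.random(30)
        assert pearson_corr(3 * x + 1, y) == pytest.approx(pearson_corr(x, y))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestAggregateRaters:
    def test_clear_majority(self):
        mat = np.array([[1], [1], [1], [1], [0], [0]])
        assert aggregate_raters(mat).tolist() == [1]

    def test_tie_is_seeded_coin(self):
        mat = np.array([[1], [1], [1], [0], [0], [0]])
        a = aggregate_raters(mat, seed=5)
        b = aggregate_raters(mat, seed=5)
        assert a.tolist() == b.tolist()
        assert a[0] in (0, 1)

    def test_tie_break_is_fair(self):
        mat = np.array([[1], [0]])
        draws = [aggregate_raters(mat, seed=s)[0] for s in range(200)]
        assert 0.35 < np.mean(draws) < 0.65

    def test_single_rater_passthrough(self):
        mat = np.array([[0, 1, 1, 0]])
        assert aggregate_raters(mat).tolist() == [0, 1, 1, 0]

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            aggregate_raters([[0, 1], [1]])


class TestEvaluateFrames:
    def test_full_report_consistency(self, rng):
        n = 300
        truth = rng.integers(0, 2, n)
        scores = np.clip(truth * 0.6 + rng.normal(0.2, 0.25, n), 0, 1)
        pred = (scores > 0.5).astype(int)
        rep = evaluate_frames(scores, pred, truth, EvalConfig(n_bootstrap=200, seed=2))
        assert rep.tp + rep.fp + rep.tn + rep.fn == n
        assert 0 <= rep.auc <= 1
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            lo, hi = rep.ci[metric]
            assert lo <= hi
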