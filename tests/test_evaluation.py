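import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from verpmark.evaluation import (
    bootstrap_auc_test,
    cluster_permutation_test,
    cohens_kappa,
    confusion_metrics,
    delong_ci,
    likelihood_ratios_from_rates,
    logistic_confound_model,
    ols_group_model,
    roc_curve,
    round_half_up,
    youden_threshold,
)
from verpmark.montage import standard_montage


def auc_pair_count_oracle(scores, is_cc, cc_low=True):
    """Exhaustive concordant-pair count, ties worth 1/2."""
    cases = [s for s, c in zip(scores, is_cc) if c]
    noncases = [s for s, c in zip(scores, is_cc) if not c]
    total = 0.0
    for c in cases:
        for n in noncases:
            concordant = c < n if cc_low else c > n
            total += 1.0 if concordant else (0.5 if c == n else 0.0)
    return total / (len(cases) * len(noncases))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([-2, -1, 1, 2], [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_curve([0.5] * 6, [True] * 3 + [False] * 3)
        assert roc.auc == 0.5

    def test_interleaved_example(self):
        roc = roc_curve([1, 3, 2, 4], [True, True, False, False])
        assert roc.auc == 0.75

    def test_one_class_absent(self):
        with pytest.raises(ValueError, match="class"):
            roc_curve([1, 2], [True, True])

    def test_curve_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_pair_count_oracle(self, data):
        n = data.draw(st.integers(4, 12))
        scores = data.draw(
            st.lists(st.integers(-3, 3), min_size=n, max_size=n)
        )
        n_cases = data.draw(st.integers(1, n - 1))
        labels = [True] * n_cases + [False] * (n - n_cases)
        roc = roc_curve(np.array(scores, float), np.array(labels))
        assert roc.auc == pytest.approx(
            auc_pair_count_oracle(scores, labels), abs=1e-12
        )


class TestYoudenThreshold:
    def test_perfect_separation_j_is_one(self):
        roc = roc_curve([-2, -1, 1, 2], [True, True, False, False])
        rule = youden_threshold(roc)
        idx = np.searchsorted(roc.thresholds, rule.threshold)
        j = roc.sensitivity[idx] + roc.specificity[idx] - 1
        assert j == 1.0

    def test_all_equal_scores_j_zero(self):
        roc = roc_curve([1.0] * 5, [True, True, False, False, False])
        rule = youden_threshold(roc)
        idx = np.searchsorted(roc.thresholds, rule.threshold)
        assert roc.sensitivity[idx] + roc.specificity[idx] - 1 == 0.0

    def test_matches_brute_force_on_toy_sets(self):
        rng = np.random.default_rng(3)
        for trial in range(25):
            scores = rng.integers(-4, 5, size=10).astype(float)
            labels = np.zeros(10, dtype=bool)
            labels[rng.choice(10, size=4, replace=False)] = True
            roc = roc_curve(scores, labels)
            rule = youden_threshold(roc)
            # oracle: enumerate every distinct threshold
            best = max(
                (
                    (
                        np.mean(scores[labels] <= t)
                        + np.mean(scores[~labels] > t) - 1,
                        np.mean(scores[~labels] > t),
                        -t,
                    )
                    for t in np.unique(scores)
                ),
            )
            idx = np.searchsorted(roc.thresholds, rule.threshold)
            j = roc.sensitivity[idx] + roc.specificity[idx] - 1
            assert j == pytest.approx(best[0], abs=1e-12)
            assert roc.specificity[idx] == pytest.approx(best[1], abs=1e-12)


class TestDelongCi:
    def test_perfect_separation_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            auc, lo, hi, se = delong_ci([-2, -1, 1, 2],
                                        [True, True, False, False])
        assert (auc, lo, hi, se) == (1.0, 1.0, 1.0, 0.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        a1, lo1, hi1, _ = delong_ci(scores, labels)
        a2, lo2, hi2, _ = delong_ci(scores, ~labels)
        assert a2 == pytest.approx(1 - a1, abs=1e-12)
        assert lo2 == pytest.approx(1 - hi1, abs=1e-9)
        assert hi2 == pytest.approx(1 - lo1, abs=1e-9)

    def test_auc_matches_roc_curve(self):
        rng = np.random.default_rng(6)
        scores = rng.integers(0, 5, size=40).astype(float)
        labels = rng.random(40) < 0.3
        auc, *_ = delong_ci(scores, labels)
        assert auc == pytest.approx(roc_curve(scores, labels).auc, abs=1e-12)

    def test_requires_two_per_class(self):
        with pytest.raises(ValueError, match="2"):
            delong_ci([1, 2, 3], [True, False, False])


class TestBootstrapAucTest:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        labels = np.arange(30) < 10
        d, p = bootstrap_auc_test(s, s, labels, n_boot=200, seed=1)
        assert d == 0.0 and p == 1.0

    def test_separating_vs_random(self):
        rng = np.random.default_rng(1)
        labels = np.arange(60) < 20
        good = np.where(labels, -1.0, 1.0) + rng.normal(0, 0.1, 60)
        noise = rng.normal(size=60)
        d, p = bootstrap_auc_test(good, noise, labels, n_boot=500, seed=2)
        assert p < 0.01

    def test_seed_stability(self):
        rng = np.random.default_rng(2)
        labels = np.arange(52) < 13
        a = np.where(labels, -0.8, 0.0) + rng.normal(0, 1, 52)
        b = np.where(labels, -0.5, 0.0) + rng.normal(0, 1, 52)
        _, p1 = bootstrap_auc_test(a, b, labels, n_boot=2000, seed=10)
        _, p2 = bootstrap_auc_test(a, b, labels, n_boot=2000, seed=99)
        assert abs(p1 - p2) < 0.02

    def test_nboot_floor(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_auc_test([1, 2], [1, 2], [True, False], n_boot=1)


class TestConfusionMetrics:
    def test_counts_and_rates(self):
        labels = [True] * 14 + [False] * 15
        preds = [True] * 12 + [False] * 2 + [False] * 12 + [True] * 3
        rep = confusion_metrics(labels, preds)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (12, 2, 12, 3)
        assert round_half_up(100 * rep.sensitivity, 1) == 85.7
        assert round_half_up(100 * rep.specificity, 1) == 80.0
        assert round_half_up(100 * rep.accuracy, 1) == 82.8

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    @given(
        tp=st.integers(1, 40), fn=st.integers(1, 40),
        tn=st.integers(1, 40), fp=st.integers(1, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities_hold_for_random_tables(self, tp, fn, tn, fp):
        labels = [True] * (tp + fn) + [False] * (tn + fp)
        preds = ([True] * tp + [False] * fn + [False] * tn + [True] * fp)
        rep = confusion_metrics(labels, preds)
        sens, spec = rep.sensitivity, rep.specificity
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))
        assert rep.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
        assert rep.lr_positive == pytest.approx(sens / (1 - spec))
        assert rep.lr_negative == pytest.approx((1 - sens) / spec)

    def test_likelihood_ratios_from_printed_rates(self):
        lr_pos, lr_neg = likelihood_ratios_from_rates("0.769", "0.846")
        assert round_half_up(lr_pos, 2) == 4.99
        assert round_half_up(lr_neg, 2) == 0.27


class TestCohensKappa:
    def test_identical_vectors(self):
        v = [True, False, True, True, False]
        assert cohens_kappa(v, v) == pytest.approx(1.0)

    def test_independent_random_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random(20_000) < 0.5
        b = rng.random(20_000) < 0.5
        assert abs(cohens_kappa(a, b)) < 0.03

    def test_hand_computed_table(self):
        # table (a,b,c,d) = (4,1,1,4): po=0.8, pe=0.5 -> kappa 0.6
        a = [True] * 5 + [False] * 5
        b = [True] * 4 + [False] + [True] + [False] * 4
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_constant_equal_ratings(self):
        with pytest.warns(UserWarning, match="constant"):
            assert cohens_kappa([True] * 4, [True] * 4) == 1.0


@pytest.fixture(scope="module")
def adjacency():
    montage = standard_montage()
    return montage.adjacency(montage.posterior)


class TestClusterPermutation:

    def test_null_data_no_clusters(self, adjacency):
        data = np.random.default_rng(0).normal(size=(10, 13, 7))
        result = cluster_permutation_test(data, data.copy(), adjacency,
                                          n_perm=100, seed=0)
        assert result.clusters == []
        assert result.min_p == 1.0

    def test_planted_effect_detected(self, adjacency):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.5, size=(12, 13, 7))
        upper = base + 2.0  # constant offset across the posterior window
        result = cluster_permutation_test(upper, base, adjacency,
                                          n_perm=1000, seed=2)
        assert result.min_p < 0.001 * 1.1  # (1+0)/(1000+1)
        assert result.clusters[0]["mass"] > 0

    def test_negative_effect_gives_negative_cluster(self, adjacency):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.5, size=(12, 13, 7))
        result = cluster_permutation_test(base - 1.5, base, adjacency,
                                          n_perm=500, seed=3)
        assert result.clusters[0]["mass"] < 0
        assert result.min_p < 0.01

    def test_requires_two_participants(self, adjacency):
        data = np.zeros((1, 13, 7))
        with pytest.raises(ValueError, match="participants"):
            cluster_permutation_test(data, data, adjacency, n_perm=10)

    def test_deterministic_under_seed(self, adjacency):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 13, 7))
        b = rng.normal(size=(8, 13, 7))
        r1 = cluster_permutation_test(a, b, adjacency, n_perm=200, seed=5)
        r2 = cluster_permutation_test(a, b, adjacency, n_perm=200, seed=5)
        assert [c["p"] for c in r1.clusters] == [c["p"] for c in r2.clusters]


class TestOlsGroupModel:
    def test_saturated_means_recovered_exactly(self):
        mpp1 = [0.5] * 4 + [0.4] * 4 + [-0.3] * 4
        groups = ["Control"] * 4 + ["DC"] * 4 + ["CC"] * 4
        res = ols_group_model(mpp1, groups)
        assert res["beta_dc"] == pytest.approx(-0.1, abs=1e-12)
        assert res["beta_cc"] == pytest.approx(-0.8, abs=1e-12)
        assert res["intercept"] == pytest.approx(0.5, abs=1e-12)

    def test_permuted_labels_null(self):
        rng = np.random.default_rng(0)
        betas = []
        groups = np.array(["Control"] * 20 + ["DC"] * 10 + ["CC"] * 10)
        y = rng.normal(size=40)
        for _ in range(100):
            betas.append(
                ols_group_model(y, rng.permutation(groups))["beta_cc"]
            )
        assert abs(np.mean(betas)) < 0.12  # ~3 SE of the permutation mean

    def test_standardized_beta_convention(self):
        rng = np.random.default_rng(1)
        y = np.concatenate(
            [rng.normal(0.5, 0.2, 20), rng.normal(0.4, 0.2, 10),
             rng.normal(-0.3, 0.2, 10)]
        )
        groups = ["Control"] * 20 + ["DC"] * 10 + ["CC"] * 10
        res = ols_group_model(y, groups)
        assert res["std_beta_cc"] == pytest.approx(
            res["beta_cc"] / np.std(y, ddof=1)
        )

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            ols_group_model([1, 2], ["CC", "DC"])


class TestLogisticConfoundModel:
    def test_all_correct_flags_separation(self):
        rng = np.random.default_rng(0)
        res = logistic_confound_model(
            np.ones(20), rng.normal(size=20), rng.normal(size=20)
        )
        assert res["separated"]

    def test_intercept_recovers_log_odds(self):
        rng = np.random.default_rng(1)
        n = 400
        correct = (rng.random(n) < 0.8).astype(float)
        res = logistic_confound_model(
            correct, rng.normal(size=n), rng.normal(size=n)
        )
        assert not res["separated"]
        est = res["params"]["intercept"]
        se = res["se"]["intercept"]
        assert abs(est - np.log(4.0)) < 2 * se + 1e-9
        assert abs(res["params"]["age_at_surgery"]) < \
            2 * res["se"]["age_at_surgery"] + 1e-9

    def test_shift_invariance_of_standardized_predictors(self):
        rng = np.random.default_rng(2)
        n = 80
        correct = (rng.random(n) < 0.7).astype(float)
        age = rng.normal(60, 20, n)
        tss = rng.normal(100, 30, n)
        r1 = logistic_confound_model(correct, age, tss)
        r2 = logistic_confound_model(correct, age + 100.0, tss)
        for key in r1["params"]:
            assert r1["params"][key] == pytest.approx(r2["params"][key],
                                                      abs=1e-8)
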