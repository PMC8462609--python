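"""Statistical layer: exact rank tests against enumeration oracles,
2x2 tests, correlation, survival and importance screening."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ctdna_concord import stats


def brute_force_u_tail(n1, n2, u_max):
    """Count labelings with U <= u_max by exhaustive enumeration."""
    n = n1 + n2
    hits = total = 0
    for group1 in itertools.combinations(range(n), n1):
        g1 = set(group1)
        u = sum(1 for i in group1 for j in range(n) if j not in g1 and i > j)
        total += 1
        hits += u <= u_max
    return hits, total


class TestExactMannWhitney:
    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (5, 5), (6, 6), (2, 7)])
    def test_distribution_matches_exhaustive_enumeration(self, n1, n2):
        counts = stats.exact_u_distribution(n1, n2)
        for u in range(0, n1 * n2 + 1, max(1, n1 * n2 // 6)):
            hits, total = brute_force_u_tail(n1, n2, u)
            assert sum(counts[: u + 1]) == hits
            assert sum(counts) == total

    def test_two_sided_p_small_case(self):
        # all C(6,3)=20 labelings; 4 have U <= 2 -> two-sided 2*4/20 = 0.4
        assert stats.mann_whitney_exact(3, 3, 2).p_two_sided == pytest.approx(0.4)

    def test_degenerate_single_observations(self):
        assert stats.mann_whitney_exact(1, 1, 0).p_two_sided == 1.0

    def test_complete_separation_20_vs_29(self):
        r = stats.mann_whitney_exact(20, 29, 0)
        assert r.p_two_sided == pytest.approx(2 / math.comb(49, 20))

    def test_u_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_exact(3, 3, 10)

    def test_non_integer_u_requires_approximation(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_exact(3, 3, 2.5)


class TestMannWhitneyFromSamples:
    def test_separated_samples_reproduce_exact_tail(self):
        x = np.arange(20)            # all smaller
        y = np.arange(100, 129)
        r = stats.mann_whitney_from_samples(x, y)
        assert r.u_statistic == 0
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(2 / math.comb(49, 20))

    def test_identical_multisets_give_central_u(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = stats.mann_whitney_from_samples(x, x.copy())
        assert r.u_statistic == pytest.approx(len(x) ** 2 / 2)
        assert r.p_two_sided > 0.9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(10, dtype=float))  # no ties
        x, y = pooled[:4], pooled[4:]
        r = stats.mann_whitney_from_samples(x, y)
        u_obs = r.u_statistic
        n1, n2 = 4, 6
        hits_lo, total = brute_force_u_tail(n1, n2, int(u_obs))
        hits_hi, _ = brute_force_u_tail(n1, n2, n1 * n2 - int(u_obs))
        expected = min(1.0, 2 * min(hits_lo, hits_hi) / total)
        assert r.p_two_sided == pytest.approx(expected)

    def test_ties_fall_back_to_corrected_normal(self):
        x = [1, 1, 2, 2, 3]
        y = [2, 3, 3, 4, 4]
        r = stats.mann_whitney_from_samples(x, y)
        assert r.method == "normal-approximation"
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_from_samples([], [1.0])


class TestContingency:
    def test_reconstructed_stage_table(self):
        stat, p = stats.pearson_chi2_2x2([[1, 9], [10, 8]])
        assert round(stat, 2) == 5.59
        assert p == pytest.approx(0.018, abs=5e-4)

    def test_reconstructed_metastasis_table(self):
        stat, _ = stats.pearson_chi2_2x2([[6, 10], [5, 6]])
        assert round(stat, 2) == 0.17

    def test_independence_gives_zero(self):
        stat, p = stats.pearson_chi2_2x2([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0

    @given(a=st.integers(1, 30), b=st.integers(1, 30),
           c=st.integers(1, 30), d=st.integers(1, 30))
    @settings(max_examples=100, deadline=None)
    def test_equals_closed_form(self, a, b, c, d):
        stat, _ = stats.pearson_chi2_2x2([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed)

    def test_zero_margin_is_error_but_fisher_defined(self):
        with pytest.raises(ValueError):
            stats.pearson_chi2_2x2([[0, 0], [3, 4]])
        assert 0 < stats.fisher_exact_2x2([[0, 0], [3, 4]]) <= 1

    def test_fisher_matches_hypergeometric_tail(self):
        p = stats.fisher_exact_2x2([[1, 9], [10, 8]])
        assert p == pytest.approx(sps.fisher_exact([[1, 9], [10, 8]])[1])


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.array([1.0, 2.5, 4.0, 7.0, 11.0, 20.0])
        rho, _ = stats.spearman(x, np.exp(x / 10))
        assert rho == pytest.approx(1.0)
        rho, _ = stats.spearman(x, -x**3)
        assert rho == pytest.approx(-1.0)

    def test_constant_input_sentinel(self):
        rho, p = stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_small_n_p_matches_permutation_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho_obs = sps.spearmanr(x, y).statistic
        hits = 0
        for perm in itertools.permutations(y):
            if abs(sps.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12:
                hits += 1
        _, p = stats.spearman(x, y)
        assert p == pytest.approx(hits / math.factorial(5))


class TestBinning:
    @pytest.mark.parametrize("k, label", [
        (0, "0"), (1, "1-2"), (2, "1-2"), (3, "3-6"),
        (6, "3-6"), (7, ">6"), (40, ">6"),
    ])
    def test_stratum_labels(self, k, label):
        assert stats.bin_matching_count(k) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stats.bin_matching_count(-1)


class TestSurvival:
    def test_product_limit_by_hand(self):
        curve = stats.km_estimator([1, 2, 3, 4], [True] * 4)
        np.testing.assert_allclose(curve.survival[-4:], [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2

    def test_no_censoring_reproduces_one_minus_ecdf(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(100, size=50)
        curve = stats.km_estimator(t, np.ones(50, dtype=bool))
        ecdf = np.array([np.mean(t <= ti) for ti in np.sort(t)])
        surv_at_events = curve.survival[np.isin(curve.times, np.sort(t))]
        np.testing.assert_allclose(surv_at_events, 1 - ecdf, atol=1e-12)

    def test_all_censored_median_sentinel(self):
        curve = stats.km_estimator([5, 6, 7], [False, False, False])
        assert math.isinf(curve.median)

    def test_identical_strata_null_logrank(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [True, True, False, True, True]
        stat, p = stats.logrank_test({"a": (t, e), "b": (t, e)})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_cox_recovers_programmed_hazard_ratio(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(math.log(2) * x)))
        cens = rng.uniform(0, 300, size=n)
        obs = np.minimum(t, cens)
        event = t <= cens
        res = stats.cox_ph(pd.DataFrame({"x": x}), obs, event)
        coef, se = res.loc["x", "coef"], res.loc["x", "se"]
        assert abs(coef - math.log(2)) < 3 * se

    def test_cox_null_covariate_calibrated(self):
        z_scores = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 120
            x = rng.standard_normal(n)
            t = rng.exponential(100, size=n)
            event = rng.random(n) < 0.8
            res = stats.cox_ph(pd.DataFrame({"x": x}), t, event)
            z_scores.append(abs(res.loc["x", "z"]))
        assert np.mean(np.array(z_scores) < 3) >= 0.95

    def test_cox_duplicated_covariate_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="rank"):
            stats.cox_ph(pd.DataFrame({"a": x, "b": x}),
                         np.arange(1, 11), [True] * 10)


class TestShadowImportance:
    def test_planted_signal_recovered(self):
        confirmed_runs = 0
        rejected_noise = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 120
            y = rng.integers(0, 2, size=n)
            cols = {"signal": y + rng.normal(0, 0.3, size=n)}
            for j in range(9):
                cols[f"noise{j}"] = rng.standard_normal(n)
            dec = stats.shadow_importance(pd.DataFrame(cols), y,
                                          n_iterations=30, rng=rng,
                                          n_estimators=60)
            confirmed_runs += dec["signal"] == "confirmed"
            rejected_noise.append(
                sum(dec[f"noise{j}"] == "rejected" for j in range(9)))
        assert confirmed_runs == 3
        assert all(r >= 8 for r in rejected_noise)

    def test_all_noise_yields_no_confirmations(self):
        no_confirm = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y = rng.integers(0, 2, size=80)
            cols = {f"n{j}": rng.standard_normal(80) for j in range(6)}
            dec = stats.shadow_importance(pd.DataFrame(cols), y,
                                          n_iterations=25, rng=rng,
                                          n_estimators=50)
            no_confirm += all(v != "confirmed" for v in dec.values())
        assert no_confirm >= 4

    def test_constant_feature_auto_rejected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=40)
        df = pd.DataFrame({"flat": np.ones(40), "x": rng.standard_normal(40)})
        dec = stats.shadow_importance(df, y, n_iterations=20, rng=rng,
                                      n_estimators=30)
        assert dec["flat"] == "rejected"

    def test_minimum_iterations_enforced(self):
        with pytest.raises(ValueError):
            stats.shadow_importance(pd.DataFrame({"x": [1.0, 2.0]}), [0, 1],
                                    n_iterations=5)


class TestDiscrimination:
    def test_perfect_separation(self):
        assert stats.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, size=2000)
        assert abs(stats.roc_auc(scores, labels) - 0.5) < 0.05

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        a1 = stats.roc_auc(scores, labels)
        a2 = stats.roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_auc_equals_rank_sum_identity(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = np.array([0] * 14 + [1] * 16)
        auc = stats.roc_auc(scores, labels)
        r = stats.mann_whitney_from_samples(scores[labels == 0],
                                            scores[labels == 1])
        n1n2 = 14 * 16
        u_pos = n1n2 - r.u_statistic  # r.u is oriented to the smaller group
        assert auc in (pytest.approx(u_pos / n1n2), pytest.approx(r.u_statistic / n1n2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("scheme", ["stratified-5-fold", "leave-one-out"])
    def test_cross_validated_discrimination_on_separable_data(self, scheme):
        rng = np.random.default_rng(6)
        n = 30
        y = np.array([0] * 15 + [1] * 15)
        df = pd.DataFrame({"f": y * 3.0 + rng.normal(0, 0.5, n)})
        res = stats.discriminate(df, y, scheme=scheme, rng=rng)
        assert res.auc > 0.9
        assert res.scheme.startswith(scheme)


class TestGroupComparisonChoice:
    def test_normal_data_uses_t_test(self):
        rng = np.random.default_rng(7)
        name, p = stats.compare_groups(rng.normal(0, 1, 40), rng.normal(2, 1, 40))
        assert name == "t-test" and p < 1e-6

    def test_skewed_data_uses_rank_test(self):
        rng = np.random.default_rng(8)
        name, _ = stats.compare_groups(rng.lognormal(0, 1.5, 40),
                                       rng.lognormal(0, 1.5, 40))
        assert name == "mann-whitney"
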