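"""Classification metrics and statistical tests, with enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from npcstage.stats import (
    acc_sen_spe,
    chi_square_test,
    clopper_pearson,
    confusion_table,
    delong_test,
    delong_variance,
    group_accuracy,
    mann_whitney_u,
    mcnemar_test,
    roc_auc_ovr,
    wilcoxon_signed_rank,
)


def pair_counting_auc(scores, labels):
    """Concordant-pair AUC oracle with mid-rank tie handling."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = ties = 0
    for p in pos:
        for q in neg:
            total += 1
            conc += p > q
            ties += p == q
    return (conc + 0.5 * ties) / total


class TestClopperPearson:
    def test_zero_and_full_successes(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    def test_interval_brackets_proportion(self):
        ci = clopper_pearson(30, 100)
        assert ci.lower < 0.3 < ci.upper

    def test_nested_in_coarser_levels(self):
        c90 = clopper_pearson(40, 90, 0.90)
        c95 = clopper_pearson(40, 90, 0.95)
        c99 = clopper_pearson(40, 90, 0.99)
        assert c99.lower <= c95.lower <= c90.lower
        assert c90.upper <= c95.upper <= c99.upper

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(1, 10, level=1.0)


class TestAccSenSpe:
    def test_identity_table_is_perfect(self):
        r = acc_sen_spe(confusion_table([1, 2, 3, 4], [1, 2, 3, 4]))
        assert r["acc"] == r["sen"] == r["spe"] == 1.0

    def test_macro_averages_uniform_random_expectation(self, rng):
        # uniform predictions on balanced classes: acc ~ 1/4, spe ~ 3/4
        n = 4000
        true = rng.integers(1, 5, n)
        pred = rng.integers(1, 5, n)
        r = acc_sen_spe(confusion_table(true, pred))
        assert abs(r["acc"] - 0.25) < 0.03
        assert abs(r["sen"] - 0.25) < 0.03
        assert abs(r["spe"] - 0.75) < 0.03

    def test_absent_class_excluded_with_warning(self):
        table = confusion_table([1, 1, 2], [1, 2, 2])
        with pytest.warns(UserWarning):
            r = acc_sen_spe(table)
        assert 0 <= r["sen"] <= 1

    def test_group_accuracy_counts(self):
        counts = np.zeros((4, 4), int)
        counts[0, 0], counts[1, 1] = 50, 76      # 126 correct early
        counts[0, 1], counts[1, 0] = 20, 20      # 166 early total
        from npcstage.stats import ConfusionTable
        ci = group_accuracy(ConfusionTable(counts), (1, 2))
        assert (ci.successes, ci.trials) == (126, 166)


class TestRocAuc:
    def test_perfectly_separable(self):
        probs = np.eye(4)[np.array([0, 1, 2, 3, 0, 1, 2, 3])]
        labels = [1, 2, 3, 4, 1, 2, 3, 4]
        assert roc_auc_ovr(probs, labels, "micro") == 1.0
        assert roc_auc_ovr(probs, labels, "macro") == 1.0

    def test_chance_level_on_label_independent_scores(self, rng):
        n = 4000
        probs = rng.dirichlet(np.ones(4), n)
        labels = rng.integers(1, 5, n)
        assert abs(roc_auc_ovr(probs, labels, "micro") - 0.5) < 0.02

    @pytest.mark.parametrize("n", range(4, 13))
    def test_micro_matches_pair_counting_oracle(self, n, rng):
        for _ in range(10):
            probs = rng.dirichlet(np.ones(4), n)
            labels = rng.integers(1, 5, n)
            onehot = np.zeros((n, 4))
            onehot[np.arange(n), labels - 1] = 1
            expected = pair_counting_auc(probs.ravel(), onehot.ravel())
            assert roc_auc_ovr(probs, labels, "micro") == pytest.approx(expected, abs=1e-12)

    def test_macro_requires_all_stages(self):
        probs = np.full((6, 4), 0.25)
        with pytest.raises(ValueError):
            roc_auc_ovr(probs, [1, 1, 2, 2, 3, 3], "macro")


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        y = np.array([0, 1] * 20)
        s = rng.random(40)
        r = delong_test(s, s, y)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        r1, r2 = delong_test(a, b, y), delong_test(b, a, y)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_variance_against_bootstrap(self, rng):
        n = 200
        y = np.array([1] * 80 + [0] * 120)
        scores = rng.random(n) + 0.8 * y
        var = delong_variance(scores, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy, ss = y[idx], scores[idx]
            if yy.sum() < 2 or (1 - yy).sum() < 2:
                continue
            boots.append(pair_counting_auc(ss, yy))
        bvar = np.var(boots, ddof=1)
        assert abs(var - bvar) / bvar < 0.15

    def test_detects_clear_auc_difference(self, rng):
        y = np.array([0, 1] * 50)
        good = y + 0.1 * rng.random(100)
        noise = rng.random(100)
        assert delong_test(good, noise, y).p_value < 0.01


class TestMcNemar:
    def test_balanced_discordants_not_significant(self):
        a = np.array([True] * 5 + [False] * 5 + [True] * 10)
        b = np.array([False] * 5 + [True] * 5 + [True] * 10)
        assert mcnemar_test(a, b).p_value == 1.0

    def test_exact_binomial_oracle_12_2(self):
        a = np.r_[np.ones(12), np.zeros(2), np.ones(30)].astype(bool)
        b = np.r_[np.zeros(12), np.ones(2), np.ones(30)].astype(bool)
        expected = 2 * sps.binom.cdf(2, 14, 0.5)
        assert mcnemar_test(a, b).p_value == pytest.approx(expected)

    def test_identical_outcomes(self):
        a = np.array([True, False, True])
        assert mcnemar_test(a, a).p_value == 1.0

    def test_exact_and_chi2_agree_on_calls_near_switchover(self, rng):
        # the corrected chi-square is a coarse stand-in for the exact
        # binomial near the switchover; they must agree on 5% calls
        for _ in range(100):
            n01, n10 = rng.integers(8, 18, 2)
            p_exact = min(1.0, 2 * sps.binom.cdf(min(n01, n10), n01 + n10, 0.5))
            stat = (abs(n01 - n10) - 1) ** 2 / (n01 + n10)
            p_chi2 = float(sps.chi2.sf(stat, 1))
            assert (p_exact < 0.05) == (p_chi2 < 0.05) or min(p_exact, p_chi2) > 0.01


class TestWilcoxon:
    def test_identical_pairs(self):
        x = np.arange(10.0)
        assert wilcoxon_signed_rank(x, x).p_value == 1.0

    def test_matches_sign_enumeration_at_n6(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.5, 1.0, 5.5, 3.2, 3.9, 7.1])
        d = x - y
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        # enumerate all 2^6 sign assignments under H0
        stats_null = [np.sum([r for r, s in zip(ranks, signs) if s])
                      for signs in itertools.product([0, 1], repeat=6)]
        mean_w = np.mean(stats_null)
        p_oracle = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12
                            for w in stats_null])
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_shift_alternative_significant(self, rng):
        x = rng.random(20)
        assert wilcoxon_signed_rank(x, x + 1.0).p_value < 0.01

    def test_exact_approx_agreement_near_switchover(self, rng):
        for n in (24, 25, 26):
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n) * 0.8
            d = x - y
            exact = sps.wilcoxon(d, method="exact").pvalue
            approx = sps.wilcoxon(d, method="approx", correction=False).pvalue
            assert abs(exact - approx) < 0.02


class TestMannWhitney:
    def test_identical_samples_u_half(self):
        x = np.arange(8.0)
        r = mann_whitney_u(x, x)
        assert r.statistic == len(x) ** 2 / 2

    def test_tiny_separated_samples_exact(self):
        r = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)

    def test_enumeration_oracle_small_n(self, rng):
        x = rng.random(4)
        y = rng.random(5)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        u_obs = sum(xi > yj for xi in x for yj in y)
        us = []
        for comb in itertools.combinations(range(len(pooled)), n1):
            xs = pooled[list(comb)]
            ys = np.delete(pooled, list(comb))
            us.append(sum(a > b for a in xs for b in ys))
        us = np.asarray(us)
        m = n1 * len(y) / 2
        p_oracle = np.mean(np.abs(us - m) >= abs(u_obs - m) - 1e-12)
        assert mann_whitney_u(x, y).p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_sample_swap_symmetry(self, rng):
        x, y = rng.random(6), rng.random(9)
        r1, r2 = mann_whitney_u(x, y), mann_whitney_u(y, x)
        assert r1.statistic + r2.statistic == pytest.approx(len(x) * len(y))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_identical_rows_give_p_one(self):
        r = chi_square_test([[10, 20, 30], [10, 20, 30]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_degrees_of_freedom(self):
        assert chi_square_test([[5, 6, 7], [8, 9, 10]]).df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 5], [0, 7]])

    def test_matches_manual_pearson_statistic(self):
        table = np.array([[20, 30], [25, 25]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert chi_square_test(table).statistic == pytest.approx(stat)
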