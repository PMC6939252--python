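from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

import arcmorph as am
from arcmorph.stats import (
    adjust_pvalues,
    fligner_killeen_test,
    mancova_allometry_test,
    manova_test,
    procrustes_variance_test,
    procrustes_variances,
    wilcoxon_size_test,
)


def enumerate_wilcoxon_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    obs_u = np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2

    n = len(pooled)
    us = []
    for idx in combinations(range(n), n_a):
        r = np.sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2
        us.append(r)
    us = np.array(us)
    mean_u = len(a) * len(b) / 2
    # two-sided: assignments at least as extreme (in |U - E[U]|)
    return np.mean(np.abs(us - mean_u) >= abs(obs_u - mean_u) - 1e-12)


class TestWilcoxon:
    def test_extreme_separation_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 0.1, verified by
        enumerating all 20 rank assignments."""
        res = wilcoxon_size_test([1, 2, 3], [4, 5, 6])
        assert res.statistic_value == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert enumerate_wilcoxon_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_agrees_with_enumeration_on_random_data(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        res = wilcoxon_size_test(a, b)
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(enumerate_wilcoxon_p(a, b), abs=1e-12)

    def test_identical_groups_tie_fallback(self):
        res = wilcoxon_size_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)
        assert res.extra["method"] == "normal_approx"

    def test_normal_approximation_matches_direct_formula(self, rng):
        """n=20 per group: W and p agree to 1e-8 with an independent
        implementation of the tie- and continuity-corrected normal
        approximation written from the textbook formulas."""
        a = rng.normal(size=20)
        b = rng.normal(loc=0.4, size=20)
        res = wilcoxon_size_test(a, b)

        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n1, n2 = len(a), len(b)
        u1 = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
        assert res.statistic_value == pytest.approx(u1, abs=1e-10)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts)
        n = n1 + n2
        sigma = np.sqrt(n1 * n2 / 12 * (n + 1 - tie_term / (n * (n - 1))))
        z = (abs(u1 - n1 * n2 / 2) - 0.5) / sigma
        p = 2 * sps.norm.sf(z)
        assert res.p_value == pytest.approx(min(p, 1.0), abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_size_test([], [1.0])


class TestFligner:
    def test_identical_groups_statistic_zero(self):
        res = fligner_killeen_test({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.statistic_value == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_normal_scores_formula(self, rng):
        """Statistic recomputed from scratch: normal scores of the ranks of
        absolute deviations from group medians, chi-squared scaled."""
        a = rng.normal(size=12)
        b = rng.normal(scale=3.0, size=15)
        res = fligner_killeen_test({"a": a, "b": b})

        devs = np.concatenate([np.abs(a - np.median(a)), np.abs(b - np.median(b))])
        ranks = sps.rankdata(devs)
        n = len(devs)
        scores = sps.norm.ppf(0.5 + ranks / (2 * (n + 1)))
        grand = scores.mean()
        groups = [scores[: len(a)], scores[len(a):]]
        num = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        stat = num / np.var(scores, ddof=1)
        assert res.statistic_value == pytest.approx(stat, abs=1e-8)
        assert res.p_value == pytest.approx(sps.chi2.sf(stat, 1), abs=1e-8)

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fligner_killeen_test({"a": [1.0], "b": [1, 2, 3]})


class TestManova:
    def test_equal_group_means_lambda_one(self, rng):
        x = rng.normal(size=(10, 2))
        scores = np.vstack([x, x])  # duplicated -> group means exactly equal
        groups = ["a"] * 10 + ["b"] * 10
        res = manova_test(scores, groups)
        assert res.extra["wilks_lambda"] == pytest.approx(1.0, abs=1e-12)
        assert res.statistic_value == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_lambda_matches_determinant_arithmetic(self, rng):
        """Wilks' lambda = det(W) / det(W+B) computed by direct determinant
        arithmetic on the SSCP matrices."""
        a = rng.normal(size=(8, 2))
        b = rng.normal(loc=0.8, size=(9, 2))
        scores = np.vstack([a, b])
        groups = ["a"] * 8 + ["b"] * 9
        res = manova_test(scores, groups)

        w = np.zeros((2, 2))
        for sub in (a, b):
            c = sub - sub.mean(axis=0)
            w += c.T @ c
        grand = scores.mean(axis=0)
        bmat = sum(
            len(sub) * np.outer(sub.mean(axis=0) - grand, sub.mean(axis=0) - grand)
            for sub in (a, b)
        )
        lam = np.linalg.det(w) / np.linalg.det(w + bmat)
        assert res.extra["wilks_lambda"] == pytest.approx(lam, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        x = rng.normal(size=(40, 3))
        x[:20] += [0.5, 0.0, -0.3]
        groups = ["a"] * 20 + ["b"] * 12 + ["c"] * 8
        res = manova_test(x, groups)

        df = pd.DataFrame(x, columns=["y1", "y2", "y3"])
        df["g"] = groups
        mv = MANOVA.from_formula("y1 + y2 + y3 ~ C(g)", data=df)
        table = mv.mv_test().results["C(g)"]["stat"]
        assert res.statistic_value == pytest.approx(
            float(table.loc["Wilks' lambda", "F Value"]), rel=1e-8
        )
        assert res.p_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), abs=1e-10
        )

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(30, 3))
        x[:15] += 0.5
        groups = ["a"] * 15 + ["b"] * 15
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        res1 = manova_test(x, groups)
        res2 = manova_test(x @ q, groups)
        assert res1.extra["wilks_lambda"] == pytest.approx(
            res2.extra["wilks_lambda"], abs=1e-9
        )

    def test_singular_covariance_instructs_reduction(self):
        x = np.zeros((12, 3))
        x[:, 0] = np.arange(12)
        groups = ["a"] * 6 + ["b"] * 6
        with pytest.raises(np.linalg.LinAlgError, match="reduce"):
            manova_test(x, groups)


class TestMancova:
    def test_exact_common_slope_interaction_zero(self, rng):
        log_size = np.linspace(3.5, 4.5, 30)
        groups = ["a"] * 15 + ["b"] * 15
        slope = np.array([0.7, -0.4])
        intercepts = {"a": np.array([0.0, 0.0]), "b": np.array([1.0, -1.0])}
        scores = np.array(
            [intercepts[g] + slope * s for g, s in zip(groups, log_size)]
        )
        # noise-free, identical slopes -> interaction SSCP ~ 0 -> F ~ 0
        res = mancova_allometry_test(scores, log_size, groups)
        assert res.statistic_value == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_interaction(self, rng):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        n = 50
        log_size = rng.normal(4.0, 0.2, n)
        groups = ["a"] * 25 + ["b"] * 25
        scores = rng.normal(size=(n, 2))
        scores[25:] += np.outer(log_size[25:] - 4.0, [0.8, -0.5])
        res = mancova_allometry_test(scores, log_size, groups)

        df = pd.DataFrame(scores, columns=["y1", "y2"])
        df["g"] = groups
        df["ls"] = log_size
        mv = MANOVA.from_formula("y1 + y2 ~ C(g) * ls", data=df)
        table = mv.mv_test().results["C(g):ls"]["stat"]
        assert res.statistic_value == pytest.approx(
            float(table.loc["Wilks' lambda", "F Value"]), rel=1e-8
        )
        assert res.p_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), abs=1e-10
        )

    def test_power_against_slope_difference(self, rng):
        """Groups whose allometric slopes differ by 1 SD of the scores per
        unit log size are detected most of the time at n=30/group."""
        rejections = 0
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            ls = r.normal(4.0, 1.0, 60)
            groups = ["a"] * 30 + ["b"] * 30
            scores = r.normal(size=(60, 2))
            scores[30:, 0] += 1.0 * (ls[30:] - 4.0)
            res = mancova_allometry_test(scores, ls, groups)
            rejections += res.p_value < 0.05
        assert rejections / 50 > 0.8

    def test_constant_log_size_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mancova_allometry_test(np.random.default_rng(0).normal(size=(20, 2)),
                                   np.full(20, 4.0), ["a"] * 10 + ["b"] * 10)


class TestProcrustesVariance:
    def test_identical_shapes_give_p_one(self):
        flat = np.tile(np.arange(6.0), (8, 1))
        groups = ["a"] * 4 + ["b"] * 4
        res = procrustes_variance_test(flat, groups, n_perm=199, seed=1)
        assert res.statistic_value == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_d_var_matches_hand_arithmetic(self):
        """3+3 toy shapes: d_var equals direct arithmetic on squared
        distances from the group mean shapes."""
        a = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 3.0]])
        b = np.array([[0.0, 1.0], [4.0, 0.0], [8.0, 5.0]])
        flat = np.vstack([a, b])
        groups = ["a"] * 3 + ["b"] * 3
        var_a = np.sum((a - a.mean(0)) ** 2) / 2
        var_b = np.sum((b - b.mean(0)) ** 2) / 2
        expected = abs(var_a - var_b)
        res = procrustes_variance_test(flat, groups, n_perm=199, seed=0)
        assert res.statistic_value == pytest.approx(expected, abs=1e-12)
        assert procrustes_variances(flat, groups) == pytest.approx(
            {"a": var_a, "b": var_b}
        )

    def test_seed_reproducible_and_stable_across_seeds(self, rng):
        flat = rng.normal(size=(24, 10))
        flat[:12] *= 1.6
        groups = ["a"] * 12 + ["b"] * 12
        p1 = procrustes_variance_test(flat, groups, n_perm=10000, seed=5).p_value
        p1b = procrustes_variance_test(flat, groups, n_perm=10000, seed=5).p_value
        p2 = procrustes_variance_test(flat, groups, n_perm=10000, seed=6).p_value
        assert p1 == p1b
        assert abs(p1 - p2) <= 0.01

    def test_small_n_perm_warns(self, rng):
        flat = rng.normal(size=(8, 4))
        with pytest.warns(UserWarning, match="small"):
            procrustes_variance_test(flat, ["a"] * 4 + ["b"] * 4, n_perm=50)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03]), [0.03])

    def test_bh_step_up_arithmetic(self):
        """(0.01, 0.02, 0.03, 0.04) with m=4: p*m/i then cumulative minimum
        from the largest rank gives 0.04 for every entry."""
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=25)
        for method in ("benjamini-hochberg", "holm", "bonferroni"):
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="sidak")
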