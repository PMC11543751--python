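import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glmmtree.stability import (
    ScoreMatrix,
    categorical_test,
    covariance_estimate,
    cumulative_score_process,
    gaussian_scores,
    inverse_sqrt,
    sup_lm,
    sup_lm_pvalue,
)


def _random_scorematrix(seed, n=40, k=2, cluster_size=1):
    rng = np.random.default_rng(seed)
    s = rng.normal(size=(n, k))
    s -= s.mean(axis=0)  # estimating equations hold at the optimum
    cluster = np.repeat(np.arange(int(np.ceil(n / cluster_size))), cluster_size)[:n]
    return ScoreMatrix(scores=s, cluster=cluster)


def brute_force_suplm(scores, J, trim, eval_mask=None):
    """Independent oracle: explicit loop over all admissible boundaries."""
    n, k = scores.shape
    Jinv = np.linalg.pinv(J)
    best = 0.0
    csum = np.zeros(k)
    for i in range(n):
        csum = csum + scores[i]
        t = (i + 1) / n
        if t < trim[0] or t > trim[1]:
            continue
        if eval_mask is not None and not eval_mask[i]:
            continue
        val = (csum @ Jinv @ csum) / n / (t * (1 - t))
        best = max(best, val)
    return best


class TestGaussianScores:
    def test_column_sums_vanish_at_fit(self, rng):
        n = 50
        t = rng.uniform(0, 4, n)
        X = np.column_stack([np.ones(n), t])
        y = 1 + 0.5 * t + rng.normal(size=n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sm = gaussian_scores(X, y, None, beta, cluster=np.arange(n))
        assert np.abs(sm.scores.sum(axis=0)).max() < 1e-6

    def test_three_observation_toy_hand_computed(self):
        # y = (1, 2, 4) at t = (0, 1, 2): OLS gives intercept 5/6, slope 3/2;
        # residuals (1/6, -1/3, 1/6); scores are residual * (1, t)
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        y = np.array([1.0, 2.0, 4.0])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, [5 / 6, 3 / 2])
        sm = gaussian_scores(X, y, np.zeros(3), beta, cluster=np.arange(3))
        expected = np.array([[1 / 6, 0.0], [-1 / 3, -1 / 3], [1 / 6, 1 / 3]])
        np.testing.assert_allclose(sm.scores, expected, atol=1e-12)

    def test_matches_numerical_gradient_of_log_density(self, rng):
        n = 20
        t = rng.uniform(0, 4, n)
        X = np.column_stack([np.ones(n), t])
        y = 1 + 0.5 * t + rng.normal(size=n)
        offset = rng.normal(size=n) * 0.1
        beta = np.linalg.lstsq(X, y - offset, rcond=None)[0]
        sigma2 = np.mean((y - offset - X @ beta) ** 2)
        sm = gaussian_scores(X, y, offset, beta, cluster=np.arange(n))

        def logdens(b):
            r = y - offset - X @ b
            return -0.5 * (r**2 / sigma2 + np.log(2 * np.pi * sigma2))

        h = 1e-6
        num = np.empty((n, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            num[:, j] = (logdens(beta + e) - logdens(beta - e)) / (2 * h)
        # scores omit the 1/sigma^2 factor of the exact gradient
        np.testing.assert_allclose(sm.scores, sigma2 * num, atol=1e-5)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            gaussian_scores(np.ones((3, 2)), np.ones(4), None, np.zeros(2), np.arange(4))


class TestCovarianceEstimate:
    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_singleton_clusters_reduce_to_observation_mode(self, seed):
        sm = _random_scorematrix(seed, cluster_size=1)
        np.testing.assert_array_equal(
            covariance_estimate(sm, "observation"), covariance_estimate(sm, "clustered")
        )

    def test_two_cluster_toy_hand_computed(self):
        s = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        sm = ScoreMatrix(scores=s, cluster=np.array([0, 0, 1, 1]))
        # cluster sums: (1, 1) and (-1, -1); J = mean of outer products
        expected = np.array([[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(covariance_estimate(sm, "clustered"), expected)
        np.testing.assert_allclose(covariance_estimate(sm, "observation"), np.eye(2) / 2)

    @given(seed=st.integers(0, 1000), csize=st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_psd(self, seed, csize):
        sm = _random_scorematrix(seed, cluster_size=csize)
        for mode in ("observation", "clustered"):
            w = np.linalg.eigvalsh(covariance_estimate(sm, mode))
            assert w.min() >= -1e-10

    def test_rank_deficient_flagged(self):
        J = np.array([[1.0, 1.0], [1.0, 1.0]])
        _, degenerate = inverse_sqrt(J)
        assert degenerate
        _, ok = inverse_sqrt(np.eye(2))
        assert not ok


class TestCumulativeProcess:
    def test_endpoint_is_zero(self, rng):
        sm = _random_scorematrix(1)
        J = covariance_estimate(sm, "observation")
        W = cumulative_score_process(sm.scores, J)
        assert np.abs(W[-1]).max() < 1e-6

    def test_scale_equivariance(self, rng):
        sm = _random_scorematrix(2)
        for c in (0.1, 7.3):
            J1 = covariance_estimate(sm, "observation")
            W1 = cumulative_score_process(sm.scores, J1)
            sm2 = ScoreMatrix(scores=c * sm.scores, cluster=sm.cluster)
            J2 = covariance_estimate(sm2, "observation")
            W2 = cumulative_score_process(sm2.scores, J2)
            np.testing.assert_allclose(W1, W2, atol=1e-8)

    def test_increments_have_unit_covariance(self):
        sm = _random_scorematrix(3, n=200)
        J = covariance_estimate(sm, "observation")
        W = cumulative_score_process(sm.scores, J)
        incr = np.diff(np.vstack([np.zeros(W.shape[1]), W]), axis=0) * np.sqrt(W.shape[0])
        emp = incr.T @ incr / W.shape[0]
        np.testing.assert_allclose(emp, np.eye(2), atol=1e-8)


class TestSupLM:
    def test_zero_scores_give_zero(self):
        W = np.zeros((30, 2))
        assert sup_lm(W) == 0.0

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_equals_brute_force_oracle(self, seed):
        sm = _random_scorematrix(seed, n=50)
        J = covariance_estimate(sm, "observation")
        W = cumulative_score_process(sm.scores, J)
        stat = sup_lm(W, trim=(0.1, 0.9))
        brute = brute_force_suplm(sm.scores, J, (0.1, 0.9))
        np.testing.assert_allclose(stat, brute, rtol=1e-10)

    def test_eval_mask_restricts_grid(self):
        sm = _random_scorematrix(9, n=50)
        J = covariance_estimate(sm, "observation")
        W = cumulative_score_process(sm.scores, J)
        mask = np.zeros(50, dtype=bool)
        mask[24] = True
        stat = sup_lm(W, eval_mask=mask)
        brute = brute_force_suplm(sm.scores, J, (0.1, 0.9), eval_mask=mask)
        np.testing.assert_allclose(stat, brute, rtol=1e-10)

    def test_empty_grid_errors(self):
        W = np.zeros((10, 2))
        with pytest.raises(ValueError):
            sup_lm(W, eval_mask=np.zeros(10, dtype=bool))
        with pytest.raises(ValueError):
            sup_lm(W, trim=(0.9, 0.1))


class TestSupLMPValue:
    def test_zero_statistic_gives_one(self):
        assert sup_lm_pvalue(0.0, k=2) == 1.0

    def test_monotone_nonincreasing(self):
        stats = [0.0, 1.0, 5.0, 10.0, 15.0, 25.0, 50.0]
        ps = [sup_lm_pvalue(s, k=2) for s in stats]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0.0 < p <= 1.0 for p in ps)

    def test_agrees_with_independent_monte_carlo(self):
        """Fresh Brownian-bridge simulation (own seed) reproduces p near 0.05."""
        rng = np.random.default_rng(2718281)
        reps, m, k = 20000, 1000, 2
        t = np.arange(1, m + 1) / m
        sel = (t >= 0.1) & (t <= 0.9)
        w = 1.0 / (t[sel] * (1 - t[sel]))
        vals = np.empty(reps)
        for start in range(0, reps, 2000):
            b = 2000
            incr = rng.standard_normal((b, m, k)) / np.sqrt(m)
            wp = np.cumsum(incr, axis=1)
            br = wp - t[None, :, None] * wp[:, -1:, :]
            ss = np.einsum("rtk,rtk->rt", br[:, sel, :], br[:, sel, :])
            vals[start : start + b] = (ss * w).max(axis=1)
        for q in (0.90, 0.95, 0.975):
            stat = np.quantile(vals, q)
            p = sup_lm_pvalue(float(stat), k=2, trim=(0.1, 0.9))
            assert abs(p - (1 - q)) < 0.01


class TestCategoricalTest:
    def _scores_with_levels(self, seed, L=3, per=20):
        rng = np.random.default_rng(seed)
        n = L * per
        s = rng.normal(size=(n, 2))
        s -= s.mean(axis=0)
        levels = np.repeat(np.arange(L), per)
        sm = ScoreMatrix(scores=s, cluster=np.arange(n))
        return sm, levels

    def test_invariant_to_level_relabeling(self):
        sm, levels = self._scores_with_levels(5)
        J = covariance_estimate(sm, "observation")
        r1 = categorical_test(sm, levels, J, variable="f")
        perm = np.array([2, 0, 1])
        r2 = categorical_test(sm, perm[levels], J, variable="f")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.df == r2.df == 2 * (3 - 1)

    def test_two_level_balanced_toy_hand_computed(self):
        sm, levels = self._scores_with_levels(6, L=2, per=15)
        J = covariance_estimate(sm, "observation")
        res = categorical_test(sm, levels, J, variable="f")
        # quadratic form of the one-level score sum: S' J^{-1} S / n * (1/t1 + 1/t2)
        S = sm.scores[levels == 0].sum(axis=0)
        n = sm.n
        expected = (S @ np.linalg.inv(J) @ S) / n * (1 / 0.5 + 1 / 0.5)
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        assert res.df == 2

    def test_constant_factor_untestable(self):
        sm, _ = self._scores_with_levels(7)
        J = covariance_estimate(sm, "observation")
        assert categorical_test(sm, np.zeros(sm.n, dtype=int), J) is None

    def test_clustered_mode_uses_subject_sums(self):
        rng = np.random.default_rng(8)
        n_subj, per = 20, 3
        s = rng.normal(size=(n_subj * per, 2))
        s -= s.mean(axis=0)
        cluster = np.repeat(np.arange(n_subj), per)
        sm = ScoreMatrix(scores=s, cluster=cluster)
        J = covariance_estimate(sm, "clustered")
        subj_levels = np.repeat(np.arange(2), n_subj // 2)
        res = categorical_test(sm, subj_levels, J, mode="clustered", variable="f")
        # oracle: same statistic from explicitly cluster-summed scores
        _, sums = sm.cluster_sums()
        S0 = sums[subj_levels == 0].sum(axis=0)
        expected = (S0 @ np.linalg.inv(J) @ S0) / n_subj * (2 / 0.5)
        assert res.statistic == pytest.approx(expected, rel=1e-10)
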