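"""Bayes factors and power: closed forms against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import triadkit as tk
from triadkit.bayes_stats import ContingencyTable, EffectSummary


def contingency_bf_quadrature(counts, a=1.0):
    """Oracle: dense numerical integration of both marginal likelihoods.

    H1: independent Beta(a, a) success probabilities per row;
    H0: one shared Beta(a, a) probability.  Binomial coefficients are kept
    (they cancel in the ratio).
    """
    y = np.asarray(counts, float)
    n = y.sum(axis=1)

    def binom_lik(p, row):
        return stats.binom.pmf(y[row, 0], n[row], p)

    prior = stats.beta(a, a)
    m1 = 1.0
    for row in range(2):
        val, _ = integrate.quad(lambda p: binom_lik(p, row) * prior.pdf(p), 0, 1,
                                limit=400, epsabs=1e-13, epsrel=1e-13)
        m1 *= val
    m0, _ = integrate.quad(lambda p: binom_lik(p, 0) * binom_lik(p, 1) * prior.pdf(p),
                           0, 1, limit=400, epsabs=1e-13, epsrel=1e-13)
    return m1 / m0


class TestContingencyBF:
    def test_strategy_by_condition_table(self):
        """1 vs 27 UD/OS classifiers at 100 ms against 0 vs 17 at 2000 ms:
        the participant-level association is absent (BF10 well below 1)."""
        res = tk.contingency_bf(ContingencyTable(np.array([[1, 27], [0, 17]])))
        assert res.bf10 == pytest.approx(0.14, abs=0.01)

    def test_proportional_rows_favor_null(self):
        res = tk.contingency_bf(ContingencyTable(np.array([[10, 10], [10, 10]])))
        assert res.bf10 < 1.0

    @pytest.mark.parametrize("counts", [
        [[1, 27], [0, 17]], [[3, 5], [7, 2]], [[0, 9], [9, 0]],
        [[12, 1], [11, 2]], [[2, 2], [2, 2]], [[40, 5], [4, 38]]])
    def test_closed_form_matches_quadrature_oracle(self, counts):
        res = tk.contingency_bf(ContingencyTable(np.array(counts)))
        assert res.bf10 == pytest.approx(contingency_bf_quadrature(counts), rel=1e-6)

    def test_invariant_to_swapping_rows_and_columns(self):
        t = np.array([[3, 11], [9, 2]])
        base = tk.contingency_bf(ContingencyTable(t)).bf10
        assert tk.contingency_bf(ContingencyTable(t[::-1, :])).bf10 == pytest.approx(base)
        assert tk.contingency_bf(ContingencyTable(t[:, ::-1])).bf10 == pytest.approx(base)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[0, 0], [3, 4]]))


class TestJZS:
    def test_identical_groups_favor_null(self):
        a = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        res = tk.jzs_ttest_bf(a, a + 1e-12)
        assert res.bf10 < 1.0

    def test_t_zero_favors_null_any_n(self):
        for n1, n2 in ((5, 5), (20, 10), (29, 17)):
            assert tk.jzs_bf_from_t(0.0, n1, n2).bf10 < 1.0

    def test_matches_monte_carlo_prior_integration(self):
        """Oracle: average the noncentral-t likelihood over 1e6 Cauchy prior
        draws instead of quadrature."""
        rng = np.random.default_rng(123)
        n1, n2 = 29, 17
        df = n1 + n2 - 2
        neff = n1 * n2 / (n1 + n2)
        scale = np.sqrt(2) / 2
        for t in (1.2, 2.7):
            res = tk.jzs_bf_from_t(t, n1, n2)
            delta = rng.standard_cauchy(1_000_000) * scale
            mc = stats.nct.pdf(t, df, delta * np.sqrt(neff)).mean() / stats.t.pdf(t, df)
            assert res.bf10 == pytest.approx(mc, rel=0.01)

    def test_directional_variant_doubles_for_large_positive_t(self):
        two = tk.jzs_bf_from_t(4.0, 25, 25, directional=False).bf10
        one = tk.jzs_bf_from_t(4.0, 25, 25, directional=True).bf10
        assert one == pytest.approx(2 * two, rel=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tk.jzs_ttest_bf([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestDienes:
    def test_null_effect_with_big_prior_mean_is_evidence_against(self):
        obs = EffectSummary(effect=0.0, se=0.02, n1=20, n2=20)
        assert tk.dienes_bf(obs, prior_mean=0.5).bf10 < 1.0

    def test_replicated_effect_with_tiny_se_is_strong_evidence(self):
        obs = EffectSummary(effect=0.4, se=0.01, n1=200, n2=200)
        assert tk.dienes_bf(obs, prior_mean=0.4).bf10 > 100.0

    @pytest.mark.parametrize("effect,se,mu", [
        (0.1, 0.04, 0.1), (0.0, 0.05, 0.2), (-0.07, 0.02, -0.1), (0.3, 0.2, 0.05)])
    def test_integral_matches_conjugate_closed_form(self, effect, se, mu):
        obs = EffectSummary(effect=effect, se=se, n1=29, n2=17)
        res = tk.dienes_bf(obs, prior_mean=mu)
        sd = abs(mu) / 2  # the default half-SD convention

        closed = stats.norm.pdf(effect, mu, np.hypot(se, sd)) / stats.norm.pdf(effect, 0, se)
        assert res.bf10 == pytest.approx(closed, abs=1e-8 * max(1, closed))
        assert res.error < 1e-8 * max(1.0, res.bf10)

    def test_scale_invariance(self):
        obs = EffectSummary(effect=0.12, se=0.05, n1=29, n2=17)
        b1 = tk.dienes_bf(obs, prior_mean=0.1).bf10
        k = 37.0
        obs2 = EffectSummary(effect=0.12 * k, se=0.05 * k, n1=29, n2=17)
        b2 = tk.dienes_bf(obs2, prior_mean=0.1 * k).bf10
        assert b1 == pytest.approx(b2, rel=1e-9)


class TestPower:
    def test_zero_effect_power_is_alpha(self):
        assert tk.power_chisq(0.0, 100, 1) == pytest.approx(0.05, abs=1e-9)
        assert tk.power_ttest(0.0, 25) == pytest.approx(0.05, abs=1e-6)

    def test_medium_large_chisq_effect_at_n46(self):
        # w = .40 at N = 46: about 80% power on 1 df
        assert 0.76 <= tk.power_chisq(0.40, 46, 1) <= 0.80

    def test_chisq_power_matches_simulation(self):
        # Power depends on the noncentrality N w^2 only; simulate at large N
        # (small w, same ncp) where the multinomial statistic is effectively
        # continuous and the noncentral chi-square is its sampling law.
        w, N, df, alpha = 0.04, 4_600, 1, 0.05
        assert tk.power_chisq(w, N, df) == pytest.approx(tk.power_chisq(0.40, 46, df))
        p0 = np.array([0.5, 0.5])
        p1 = p0 + np.array([1, -1]) * (w / 2)  # chi-square effect size w
        assert np.allclose(np.sum((p1 - p0) ** 2 / p0), w ** 2)
        rng = np.random.default_rng(5)
        reps = 100_000
        counts = rng.multinomial(N, p1, size=reps)
        expected = N * p0
        x2 = (((counts - expected) ** 2) / expected).sum(axis=1)
        rate = (x2 > stats.chi2.ppf(1 - alpha, df)).mean()
        se = np.sqrt(rate * (1 - rate) / reps)
        assert abs(tk.power_chisq(w, N, df) - rate) < 2 * se + 1e-3

    def test_ttest_power_matches_simulation(self):
        d, n = 0.83, 25
        rng = np.random.default_rng(6)
        reps = 100_000
        a = rng.normal(d, 1.0, size=(reps, n))
        b = rng.normal(0.0, 1.0, size=(reps, n))
        t, p = stats.ttest_ind(a, b, axis=1)
        rate = (p < 0.05).mean()
        se = np.sqrt(rate * (1 - rate) / reps)
        assert abs(tk.power_ttest(d, n) - rate) < 2 * se + 1e-3


class TestBlockTrend:
    @staticmethod
    def make_trajectory(fun, noise=0.0, rng=None):
        rows = []
        for cond, tl in ((100, 0.0), (2000, 1.0)):
            for block in range(1, 13):
                y = fun(block, tl)
                if noise:
                    y += rng.normal(0, noise)
                rows.append({"condition_ms": cond, "block": block, "ud_prop": y})
        return pd.DataFrame(rows)

    def test_residual_df_is_20(self):
        traj = self.make_trajectory(lambda b, t: 0.1 + 0.01 * b - 0.05 * t,
                                    noise=0.01, rng=np.random.default_rng(0))
        out = tk.block_trend_ols(traj)
        assert out.attrs["df_resid"] == 20
        assert set(out.index) == {"const", "block", "time_long", "block_x_time"}

    def test_exact_plane_gives_zero_p(self):
        traj = self.make_trajectory(lambda b, t: 0.2 + 0.01 * b - 0.1 * t - 0.005 * b * t)
        out = tk.block_trend_ols(traj)
        assert out.loc["time_long", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_null_interaction_rarely_significant(self):
        hits = 0
        for seed in range(20):
            traj = self.make_trajectory(lambda b, t: 0.1, noise=0.05,
                                        rng=np.random.default_rng(seed))
            out = tk.block_trend_ols(traj)
            hits += abs(out.loc["block_x_time", "t"]) > 2.0
        assert hits <= 2  # |t| < 2 in >= 90% of null runs
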