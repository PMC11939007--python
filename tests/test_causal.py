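import numpy as np
import pytest

from bimesurv.causal import (
    SurvivalCurve, cox_hr, fit_propensity, integrated_brier, iptw_weights,
    km_curve, logrank_test, psm_match, risk_difference, rmst, smd,
)


@pytest.fixture()
def toy_curve():
    # the hand product-limit example: times (2,3,3,5), events (1,1,0,1)
    return km_curve(np.array([2.0, 3.0, 3.0, 5.0]), np.array([1, 1, 0, 1]))


class TestKaplanMeier:
    def test_hand_product_limit(self, toy_curve):
        assert toy_curve.at(2.0) == pytest.approx(0.75)
        assert toy_curve.at(3.0) == pytest.approx(0.5)
        assert toy_curve.at(5.0) == pytest.approx(0.0)
        assert toy_curve.at(1.9) == pytest.approx(1.0)

    def test_all_censored_is_flat_one(self):
        c = km_curve(np.arange(1.0, 6.0), np.zeros(5, int))
        assert np.all(c.surv == 1.0)

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200)
        e = rng.binomial(1, 0.7, 200)
        c1 = km_curve(t, e)
        c2 = km_curve(t, e, weights=np.ones(200))
        np.testing.assert_allclose(c1.surv, c2.surv, atol=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(10, 150), 1) + 0.1
        e = rng.binomial(1, 0.6, 150)
        ours = km_curve(t, e)
        km = KaplanMeierFitter().fit(t, e)
        grid = np.unique(t)
        theirs = km.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours.at(grid), theirs, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_curve(np.array([]), np.array([]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.tile(np.arange(1.0, 11.0), 2)
        e = np.tile(np.array([1, 0] * 5), 2)
        g = np.repeat([0, 1], 10)
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # brute-force hypergeometric sums written out explicitly
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        g = np.array([1, 0, 1, 1, 0, 0])
        O = E = V = 0.0
        for u in t[e == 1]:
            at = t >= u
            n_tot, n1 = at.sum(), (at & (g == 1)).sum()
            d = ((t == u) & (e == 1)).sum()
            d1 = ((t == u) & (e == 1) & (g == 1)).sum()
            O += d1
            E += d * n1 / n_tot
            if n_tot > 1:
                V += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx((O - E) ** 2 / V)

    def test_matches_lifelines_unweighted(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        t = np.concatenate([rng.exponential(10, 80), rng.exponential(14, 70)])
        e = rng.binomial(1, 0.7, 150)
        g = np.repeat([0, 1], [80, 70])
        stat, p = logrank_test(t, e, g)
        res = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert stat == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_label_swap_invariant(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 60)
        e = rng.binomial(1, 0.8, 60)
        g = rng.binomial(1, 0.5, 60)
        assert logrank_test(t, e, g)[0] == pytest.approx(
            logrank_test(t, e, 1 - g)[0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.arange(1.0, 5.0), np.ones(4, int), np.zeros(4))


class TestRmstAndRiskDifference:
    def test_step_integral_hand_value(self, toy_curve):
        # 2x1 + 1x0.75 + 2x0.5 = 3.75
        assert rmst(toy_curve, 5.0) == pytest.approx(3.75)

    def test_exponential_closed_form(self):
        lam = 0.03
        grid = np.linspace(0, 200, 40001)
        c = SurvivalCurve(grid, np.exp(-lam * grid))
        expected = (1 - np.exp(-lam * 120.0)) / lam
        assert rmst(c, 120.0) == pytest.approx(expected, abs=1e-2)

    def test_flat_curve_gives_tau(self):
        c = SurvivalCurve(np.array([0.0, 50.0]), np.array([1.0, 1.0]))
        assert rmst(c, 77.0) == pytest.approx(77.0)

    def test_additivity_of_step_integral(self, toy_curve):
        total = rmst(toy_curve, 5.0)
        head = rmst(toy_curve, 3.0)
        # tail area on [3, 5]: S = 0.5 throughout
        assert head + 0.5 * 2.0 == pytest.approx(total)

    @pytest.mark.parametrize("sa, sb, expected", [(0.8, 0.6, 20.0), (0.5, 0.5, 0.0)])
    def test_risk_difference_arithmetic(self, sa, sb, expected):
        ca = SurvivalCurve(np.array([0.0, 1.0]), np.array([1.0, sa]))
        cb = SurvivalCurve(np.array([0.0, 1.0]), np.array([1.0, sb]))
        assert risk_difference(ca, cb, 2.0) == pytest.approx(expected)
        assert -100.0 <= risk_difference(ca, cb, 2.0) <= 100.0


class TestSmd:
    def test_identical_groups_zero(self):
        x = np.tile(np.arange(10.0), 2)
        g = np.repeat([0, 1], 10)
        assert smd(x, g) == pytest.approx(0.0, abs=1e-12)

    def test_binary_hand_value(self):
        # p1=0.6, p0=0.4 -> 0.2 / sqrt((0.24+0.24)/2) = 0.40825
        x = np.concatenate([np.repeat([1, 0], [60, 40]), np.repeat([1, 0], [40, 60])])
        g = np.repeat([1, 0], 100)
        assert smd(x, g) == pytest.approx(0.2 / np.sqrt(0.24), abs=1e-6)

    def test_weights_that_equalize_means(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        g = np.array([1, 1, 0, 0])
        w = np.array([1.0, 1.0, 1.0, 1.0])
        base = smd(x, g, w)
        assert base == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert smd(np.ones(10), np.repeat([0, 1], 5)) == 0.0


class TestPropensityAndWeights:
    def test_independent_indicator_scores_near_prevalence(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3000, 3))
        ind = rng.binomial(1, 0.3, 3000)
        fit = fit_propensity(X, ind)
        se = np.sqrt(0.3 * 0.7 / 3000)
        assert abs(fit.scores.mean() - ind.mean()) < 3 * se

    def test_two_by_two_closed_form(self):
        # logit(P(ind=1|x)) from cell proportions: x binary, 4 cells
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [30, 10, 20, 40])
        ind = np.repeat([0, 1, 0, 1], [30, 10, 20, 40])
        fit = fit_propensity(x[:, None], ind)
        # P(1|x=0) = 10/40, P(1|x=1) = 40/60
        np.testing.assert_allclose(
            np.unique(np.round(fit.scores, 10)), [0.25, 2 / 3], atol=1e-6)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        ind = rng.binomial(1, 0.5, 50)
        X2 = np.vstack([X, X[:10]])
        ind2 = np.concatenate([ind, ind[:10]])
        fit = fit_propensity(X2, ind2)
        np.testing.assert_allclose(fit.scores[:10], fit.scores[50:], atol=1e-10)

    def test_separation_raises_naming_covariate(self):
        x = np.arange(40.0)
        ind = (x > 19.5).astype(int)
        with pytest.raises(RuntimeError, match="sep"):
            fit_propensity(x[:, None], ind, names=["sep_var"])

    @pytest.mark.parametrize("score, ind, expected", [
        (0.5, 1, 2.0), (0.5, 0, 2.0), (0.8, 1, 1.25)])
    def test_unstabilized_weight_arithmetic(self, score, ind, expected):
        from bimesurv.causal import PropensityFit

        fit = PropensityFit(coef=np.zeros(1), names=["c"],
                            scores=np.array([score]))
        w = iptw_weights(fit, np.array([ind]), stabilized=False)
        assert w[0] == pytest.approx(expected)

    def test_stabilized_weights_sum_near_n(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(1000, 2))
        ind = rng.binomial(1, 1 / (1 + np.exp(-X[:, 0])), 1000)
        fit = fit_propensity(X, ind)
        w = iptw_weights(fit, ind, stabilized=True)
        assert w.sum() == pytest.approx(1000, rel=0.05)


class TestMatching:
    def _fit(self, scores):
        from bimesurv.causal import PropensityFit

        return PropensityFit(coef=np.zeros(1), names=["c"],
                             scores=np.asarray(scores))

    def test_equal_distributions_all_matched(self):
        scores = np.tile([0.2, 0.4, 0.6], 2)
        ind = np.repeat([1, 0], 3)
        m = psm_match(self._fit(scores), ind)
        assert len(m.pairs) == 3

    def test_greedy_order_enumeration(self):
        # group1 {0.2, 0.9}, group0 {0.25, 0.5}: 0.9 grabs 0.5, 0.2 gets 0.25
        scores = np.array([0.2, 0.9, 0.25, 0.5])
        ind = np.array([1, 1, 0, 0])
        m = psm_match(self._fit(scores), ind)
        assert sorted(m.pairs) == [(0, 2), (1, 3)]

    def test_disjoint_ranges_with_caliper_rejected(self):
        scores = np.array([0.05, 0.06, 0.9, 0.95])
        ind = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError, match="caliper"):
            psm_match(self._fit(scores), ind, caliper=0.01)

    def test_without_replacement(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0.2, 0.8, 60)
        ind = rng.binomial(1, 0.4, 60)
        m = psm_match(self._fit(scores), ind)
        used = [i for p in m.pairs for i in p]
        assert len(used) == len(set(used))


class TestCoxHazardRatio:
    def test_matches_brute_force(self):
        from test_coxph import brute_force_cox

        rng = np.random.default_rng(11)
        n = 50
        ind = rng.binomial(1, 0.5, n)
        Z = rng.normal(size=(n, 1))
        T = rng.exponential(1 / np.exp(0.5 * ind - 0.3 * Z[:, 0]))
        t = np.minimum(T, rng.exponential(2, n))
        e = (T <= t + 1e-12).astype(int)
        hr, ci, fit = cox_hr(Z, t, e, ind)
        oracle = brute_force_cox(np.column_stack([ind, Z]), t, e)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-6)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(12)
        n = 120
        ind = rng.binomial(1, 0.5, n)
        t = rng.exponential(10 / (1 + ind), n)
        e = np.ones(n, int)
        hr1, _, _ = cox_hr(None, t, e, ind)
        hr2, _, _ = cox_hr(None, t, e, 1 - ind)
        assert hr1 == pytest.approx(1 / hr2, rel=1e-8)

    def test_null_simulation_ci_coverage(self):
        # indicator independent of outcome: 95% CI covers 1 in >= 90% of runs
        rng = np.random.default_rng(13)
        cover = 0
        reps = 50
        for _ in range(reps):
            n = 2000
            ind = rng.binomial(1, 0.5, n)
            t = rng.exponential(10, n)
            e = rng.binomial(1, 0.7, n)
            _, (lo, hi), _ = cox_hr(None, t, e, ind)
            cover += lo <= 1.0 <= hi
        assert cover >= 0.9 * reps


class TestIntegratedBrier:
    def test_perfect_prediction_zero(self):
        t = np.array([3.0, 6.0, 9.0])
        e = np.ones(3, int)
        grid = np.linspace(0.5, 8.5, 17)
        curves = []
        for ti in t:
            times = np.array([0.0, ti])
            curves.append(SurvivalCurve(times, np.array([1.0, 0.0])))
        assert integrated_brier(curves, t, e, grid) == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_prediction(self):
        t = np.array([3.0, 6.0, 9.0, 12.0])
        e = np.ones(4, int)
        grid = np.linspace(0.5, 11.5, 23)
        curves = [SurvivalCurve(np.array([0.0]), np.array([0.5]))] * 4
        assert integrated_brier(curves, t, e, grid) == pytest.approx(0.25, abs=1e-12)

    def test_censored_toy_matches_hand_ipcw_sum(self):
        # 5 subjects, one censored; expected value computed by writing the
        # IPCW sum out longhand at each grid point
        t = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        e = np.array([1, 0, 1, 1, 1])
        pred = [SurvivalCurve(np.array([0.0]), np.array([s]))
                for s in (0.9, 0.8, 0.6, 0.5, 0.3)]
        grid = np.array([3.0, 6.0])
        G = km_curve(t, 1 - e)          # censoring survival

        def hand_bs(tp):
            total = 0.0
            for i in range(5):
                s = pred[i].at(tp)
                if t[i] <= tp and e[i] == 1:
                    total += (0.0 - s) ** 2 / G.at(t[i] - 1e-9)
                elif t[i] > tp:
                    total += (1.0 - s) ** 2 / G.at(tp)
            return total / 5

        expected = np.trapezoid([hand_bs(3.0), hand_bs(6.0)], grid) / 3.0
        assert integrated_brier(pred, t, e, grid) == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_survival_without_censoring(self):
        from sksurv.metrics import integrated_brier_score
        from sksurv.util import Surv

        rng = np.random.default_rng(14)
        n = 80
        t = rng.exponential(10, n) + 1
        e = np.ones(n, int)
        grid = np.linspace(np.quantile(t, 0.1), np.quantile(t, 0.8), 15)
        s_vals = rng.uniform(0.2, 0.95, n)
        curves = [SurvivalCurve(np.array([0.0]), np.array([s])) for s in s_vals]
        ours = integrated_brier(curves, t, e, grid)
        y = Surv.from_arrays(e.astype(bool), t)
        preds = np.tile(s_vals[:, None], (1, len(grid)))
        theirs = integrated_brier_score(y, y, preds, grid)
        assert ours == pytest.approx(theirs, rel=1e-6)
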