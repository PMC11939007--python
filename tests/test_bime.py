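import warnings

import numpy as np
import pytest

from bimesurv.bime import (
    BimeLossParts, BimeRecommender, cox_neg_partial_loglik,
    mixture_log_hazard, time_at_risk,
)
from bimesurv.causal import SurvivalCurve


def _toy_fit_data(n=250, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    arm = rng.binomial(1, 0.5, n)
    lam = np.exp(0.5 * X[:, 0] - 0.4 * arm * X[:, 1]) / 40.0
    T = rng.exponential(1 / lam)
    C = rng.exponential(80, n)
    t = np.round(np.minimum(T, C), 1) + 0.1
    e = (T <= C).astype(int)
    return X, np.column_stack([t, e]), arm


@pytest.fixture(scope="module")
def quick_fit():
    X, y, arm = _toy_fit_data()
    est = BimeRecommender(k=2, alpha=0.1, n_folds=None, max_iter=300,
                          e_step_every=50, patience=10000, batch_size=128,
                          random_state=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y, arm)
    return est, X, y, arm


class TestCoxLossUnit:
    def test_averaged_two_subject_value(self):
        # unnormalized -ll = log 2 over 2 events -> log(2)/2 per event
        val = cox_neg_partial_loglik(np.zeros(2), np.array([1.0, 2.0]),
                                     np.array([1, 1]))
        assert val == pytest.approx(np.log(2.0) / 2)

    def test_no_events_warns_and_zero(self):
        with pytest.warns(UserWarning):
            assert cox_neg_partial_loglik(np.ones(3), np.arange(1.0, 4.0),
                                          np.zeros(3, int)) == 0.0

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(2)
        eta = rng.normal(size=30)
        t = rng.exponential(5, 30) + 0.1
        e = rng.binomial(1, 0.6, 30)
        a = cox_neg_partial_loglik(eta, t, e)
        b = cox_neg_partial_loglik(eta + 11.3, t, e)
        assert a == pytest.approx(b, abs=1e-9)


class TestMixtureLogHazard:
    def test_single_component_passthrough(self):
        f = np.array([[0.7], [-0.2]])
        logits = np.zeros((2, 1))
        eta, _, gates = mixture_log_hazard(logits, f)
        np.testing.assert_allclose(eta, f[:, 0])
        np.testing.assert_allclose(gates, 1.0)

    def test_equal_components_collapse(self):
        f = np.full((3, 4), 0.3)
        logits = np.random.default_rng(0).normal(size=(3, 4))
        eta, _, gates = mixture_log_hazard(logits, f)
        np.testing.assert_allclose(eta, 0.3, atol=1e-12)
        np.testing.assert_allclose(gates.sum(1), 1.0)

    def test_hand_mixture_value(self):
        # gates (0.3, 0.7), f = (0, 1): eta = log(0.3 + 0.7 e)
        logits = np.log(np.array([[0.3, 0.7]]))
        f = np.array([[0.0, 1.0]])
        eta, _, _ = mixture_log_hazard(logits, f)
        assert eta[0] == pytest.approx(np.log(0.3 + 0.7 * np.e))


class TestTimeAtRisk:
    def test_exponential_inversion(self):
        grid = np.linspace(0, 200, 4001)
        lam = np.log(10) / 120.0   # S(120) = 0.10
        c = SurvivalCurve(grid, np.exp(-lam * grid))
        assert time_at_risk(c, 0.10, 200.0) == pytest.approx(120.0, abs=0.1)

    def test_cap_when_never_reached(self):
        c = SurvivalCurve(np.array([0.0, 100.0]), np.array([1.0, 0.9]))
        assert time_at_risk(c, 0.10, 120.0) == 120.0

    def test_step_curve_inversion(self):
        c = SurvivalCurve(np.array([0.0, 10.0]), np.array([1.0, 0.05]))
        assert time_at_risk(c, 0.10, 120.0) == pytest.approx(10.0, abs=1e-9)

    def test_bad_threshold_rejected(self):
        c = SurvivalCurve(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            time_at_risk(c, 1.5, 120.0)


class TestLossDecomposition:
    def test_parts_identity_on_random_batches(self, quick_fit):
        est, X, y, arm = quick_fit
        for rec in est.training_log_:
            parts = BimeLossParts(**{k: rec[k] for k in
                                     ("lcox_t0", "lcox_t1", "ipm", "q",
                                      "alpha", "q_t0", "q_t1", "total")})
            assert parts.identity_residual() < 1e-10

    def test_all_censored_batch_cox_terms_zero(self, quick_fit):
        est, X, y, arm = quick_fit
        n = 60
        Xb = X[:n]
        tb = y[:n, 0]
        eb = np.zeros(n, int)
        zb = np.zeros((n, est.m_samples), int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts = est._batch_loss(Xb, tb, eb, arm[:n], zb, train=False)
        assert parts.lcox_t0 == 0.0
        assert parts.lcox_t1 == 0.0
        assert parts.total == pytest.approx(
            parts.alpha * parts.ipm + parts.q_t0 + parts.q_t1, abs=1e-10)


class TestFittedModel:
    def test_survival_curves_are_valid(self, quick_fit):
        est, X, _, _ = quick_fit
        for a in (0, 1):
            for c in est.predict_survival_function(X[:8], a):
                assert c.surv[0] == pytest.approx(1.0, abs=1e-9)
                assert np.all(np.diff(c.surv) <= 1e-12)
                assert c.surv.min() >= 0.0

    def test_prediction_deterministic_and_row_equivariant(self, quick_fit):
        est, X, _, _ = quick_fit
        ite1 = est.predict_ite(X[:20])
        ite2 = est.predict_ite(X[:20])
        np.testing.assert_allclose(ite1, ite2)
        perm = np.random.default_rng(0).permutation(20)
        np.testing.assert_allclose(est.predict_ite(X[:20][perm]), ite1[perm],
                                   atol=1e-10)

    def test_tie_rule_prefers_nsm(self, quick_fit):
        est, X, _, _ = quick_fit
        ite = est.predict_ite(X[:50])
        rec = est.predict(X[:50])
        np.testing.assert_array_equal(rec, (ite > 0).astype(int))

    def test_same_seed_identical_fit(self):
        X, y, arm = _toy_fit_data(n=150, seed=3)
        kw = dict(k=2, alpha=0.1, n_folds=None, max_iter=120, e_step_every=40,
                  batch_size=64, random_state=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = BimeRecommender(**kw).fit(X, y, arm)
            b = BimeRecommender(**kw).fit(X, y, arm)
        for pa, pb in zip(a.encoders_[0].params, b.encoders_[0].params):
            np.testing.assert_array_equal(pa, pb)
        np.testing.assert_allclose(a.predict_ite(X), b.predict_ite(X))

    def test_running_min_of_training_loss_nonincreasing(self, quick_fit):
        est, *_ = quick_fit
        totals = [r["total"] for r in est.training_log_]
        running = np.minimum.accumulate(totals)
        assert np.all(np.diff(running) <= 0)
        assert running[-1] < totals[0]

    def test_invalid_arm_rejected(self, quick_fit):
        est, X, _, _ = quick_fit
        with pytest.raises(ValueError):
            est.predict_survival_function(X[:2], arm=2)

    def test_single_arm_data_rejected(self):
        X, y, arm = _toy_fit_data(n=100)
        with pytest.raises(ValueError, match="arm"):
            BimeRecommender(n_folds=None).fit(X, y, np.zeros(100, int))

    def test_sklearn_params_roundtrip(self):
        est = BimeRecommender(k=4, alpha=0.5)
        params = est.get_params()
        est2 = BimeRecommender().set_params(**params)
        assert est2.k == 4 and est2.alpha == 0.5


class TestCheckpoint:
    def test_save_load_roundtrip(self, quick_fit, tmp_path):
        est, X, _, _ = quick_fit
        path = tmp_path / "model.npz"
        est.save(path)
        back = BimeRecommender.load(path)
        np.testing.assert_allclose(back.predict_ite(X[:15]),
                                   est.predict_ite(X[:15]), atol=1e-10)


class TestArchitecturalInvariants:
    def test_arm_label_swap_flips_recommendations(self):
        """Refitting with swapped treatment labels flips the recommended
        arm for >= 85% of patients (ties break toward NSM on both fits)."""
        from bimesurv.simulate import generate_cohort, strong_heterogeneity_config
        from bimesurv.cohort import build_design_matrix

        cohort, _ = generate_cohort(strong_heterogeneity_config(n=1500, seed=6))
        X, _, _ = build_design_matrix(cohort, standardize=False)
        t, e = cohort.survival_arrays()
        y = np.column_stack([t, e])
        arm = cohort.treatment
        kw = dict(n_folds=None, max_iter=1500, patience=800, e_step_every=100,
                  random_state=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = BimeRecommender(**kw).fit(X, y, arm)
            b = BimeRecommender(**kw).fit(X, y, 1 - arm)
        rec_a = a.predict(X)
        rec_b = b.predict(X)
        # arm labels swapped: model b's "arm 1" is model a's "arm 0"
        assert (rec_a == 1 - rec_b).mean() >= 0.85

    def test_balancing_penalty_reduces_latent_ipm(self):
        """With alpha > 0 the latent arm distributions end up closer (in
        Sinkhorn divergence) than without balancing: median over 5 seeds."""
        from bimesurv._sinkhorn import sinkhorn_divergence
        from bimesurv.simulate import generate_cohort, strong_heterogeneity_config
        from bimesurv.cohort import build_design_matrix

        gaps = {0.0: [], 0.5: []}
        for seed in range(5):
            cohort, _ = generate_cohort(strong_heterogeneity_config(n=1000,
                                                                    seed=20 + seed))
            X, _, _ = build_design_matrix(cohort, standardize=False)
            t, e = cohort.survival_arrays()
            y = np.column_stack([t, e])
            arm = cohort.treatment
            for alpha in gaps:
                est = BimeRecommender(alpha=alpha, n_folds=None, max_iter=800,
                                      patience=10000, e_step_every=200,
                                      random_state=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X, y, arm)
                Xs = (X - est.mean_) / est.scale_
                phi = est._encode(Xs, 0, train=False)
                div = sinkhorn_divergence(phi[arm == 1][:150], phi[arm == 0][:150],
                                          eps=1.0)
                gaps[alpha].append(div)
        assert np.median(gaps[0.5]) < np.median(gaps[0.0])
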