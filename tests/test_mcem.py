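import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eivfit import (
    GlmFitter,
    MeasurementErrorSpec,
    PriorSpec,
    WeightMatrix,
    compute_importance_weights,
    draw_imputations,
    effective_sample_size,
    initial_prior,
    m_step,
    observed_loglik,
    run_mcem,
    update_prior,
)
from eivfit.mcem import stack_imputed_data


class TestDrawImputations:
    def test_zero_error_reproduces_observed_values(self, rng):
        data = pd.DataFrame({"w": rng.standard_normal(30)})
        spec = MeasurementErrorSpec(["w"], 0.0)
        imps = draw_imputations(data, spec, B=5, seed=1)
        np.testing.assert_array_equal(
            imps.values, np.broadcast_to(data["w"].to_numpy()[None, :, None],
                                         (5, 30, 1)))

    def test_same_seed_is_bitwise_identical(self, rng):
        data = pd.DataFrame({"w": rng.standard_normal(30)})
        spec = MeasurementErrorSpec(["w"], 0.4)
        a = draw_imputations(data, spec, B=8, seed=42)
        b = draw_imputations(data, spec, B=8, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draw_variance_matches_error_variance(self, rng):
        """Pooled sample variance of w - x~ recovers sigma_u^2 = 0.25."""
        data = pd.DataFrame({"w": rng.standard_normal(1000)})
        spec = MeasurementErrorSpec(["w"], 0.25)
        imps = draw_imputations(data, spec, B=200, seed=3)
        pooled = np.var(imps.draws)
        assert 0.23 <= pooled <= 0.27

    def test_values_are_w_minus_draws(self, rng):
        data = pd.DataFrame({"w": rng.standard_normal(50),
                             "z": rng.standard_normal(50)})
        spec = MeasurementErrorSpec(["w"], 0.1)
        imps = draw_imputations(data, spec, B=4, seed=0)
        np.testing.assert_allclose(
            imps.values, data["w"].to_numpy()[None, :, None] - imps.draws)

    def test_non_psd_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            MeasurementErrorSpec(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestImportanceWeights:
    def test_zero_error_gives_uniform_rows(self, logistic_data, quad_fitter):
        y, _, data = logistic_data
        spec = MeasurementErrorSpec(["w"], 0.0)
        imps = draw_imputations(data, spec, B=7, seed=0)
        prior = initial_prior(data, spec)
        wts = compute_importance_weights(y, imps, quad_fitter, prior,
                                         np.array([0.5, 1.0, -0.3]), data)
        np.testing.assert_allclose(wts.q, 1.0 / 7, atol=1e-14)

    def test_single_imputation_weight_is_one(self, logistic_data, quad_fitter,
                                             me_spec):
        y, _, data = logistic_data
        imps = draw_imputations(data, me_spec, B=1, seed=0)
        prior = initial_prior(data, me_spec)
        wts = compute_importance_weights(y, imps, quad_fitter, prior,
                                         np.array([0.5, 1.0, -0.3]), data)
        np.testing.assert_array_equal(wts.q, 1.0)

    def test_two_atom_hand_oracle(self):
        """n=1, B=2 binomial-logit weights against direct formula evaluation.

        With beta=(0,1), y=1 and imputed values {0, 1} under an N(0,1)
        prior, the unnormalised weights are (0.5*phi(0), e/(1+e)*phi(1)).
        """
        from eivfit.types import ImputationSet

        data = pd.DataFrame({"w": [0.5]})
        f = GlmFitter("binomial", ["w"])
        f.builder.freeze(data)
        vals = np.array([[[0.0]], [[1.0]]])          # (B=2, n=1, p=1)
        imps = ImputationSet(values=vals, draws=0.5 - vals, seed=0,
                             columns=("w",))
        prior = PriorSpec(mean=[0.0], cov=[[1.0]])
        beta = np.array([0.0, 1.0])
        wts = compute_importance_weights(np.array([1.0]), imps, f, prior,
                                         beta, data)
        a = np.array([0.5 * stats.norm.pdf(0.0),
                      (np.e / (1 + np.e)) * stats.norm.pdf(1.0)])
        np.testing.assert_allclose(wts.q[0], a / a.sum(), atol=1e-10)
        assert wts.q[0, 0] == pytest.approx(0.530, abs=1e-3)

    def test_weight_rows_sum_to_one(self, logistic_data, quad_fitter, me_spec):
        y, _, data = logistic_data
        imps = draw_imputations(data, me_spec, B=20, seed=5)
        prior = initial_prior(data, me_spec)
        wts = compute_importance_weights(y, imps, quad_fitter, prior,
                                         np.array([0.5, 1.0, -0.3]), data)
        np.testing.assert_allclose(wts.q.sum(axis=1), 1.0, atol=1e-12)


class TestUpdatePrior:
    def test_uniform_single_imputation_recovers_sample_moments(self, rng):
        x = rng.standard_normal((1, 40, 1)) + 2.0
        from eivfit.types import ImputationSet

        imps = ImputationSet(values=x, draws=np.zeros_like(x), seed=0,
                             columns=("w",))
        wts = WeightMatrix(q=np.ones((40, 1)))
        prior = update_prior(imps, wts)
        np.testing.assert_allclose(prior.mean, x[0, :, 0].mean(), atol=1e-12)
        np.testing.assert_allclose(prior.cov[0, 0],
                                   np.var(x[0, :, 0]), rtol=1e-6)

    def test_concentrated_weights_pick_one_replicate(self, rng):
        from eivfit.types import ImputationSet

        x = rng.standard_normal((3, 50, 1))
        imps = ImputationSet(values=x, draws=np.zeros_like(x), seed=0,
                             columns=("w",))
        q = np.zeros((50, 3))
        q[:, 1] = 1.0
        prior = update_prior(imps, WeightMatrix(q=q))
        np.testing.assert_allclose(prior.mean, x[1, :, 0].mean(), atol=1e-12)
        np.testing.assert_allclose(prior.cov[0, 0], np.var(x[1, :, 0]),
                                   rtol=1e-6)

    def test_moment_recovery_from_simulation(self, rng):
        """Prior update recovers the generating mean N(2, 1.5) within 3 SE."""
        n = 500
        x = rng.normal(2.0, np.sqrt(1.5), n)
        w = x + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"w": w})
        spec = MeasurementErrorSpec(["w"], 0.25)
        imps = draw_imputations(data, spec, B=50, seed=9)
        q = np.full((n, 50), 1.0 / 50)
        prior = update_prior(imps, WeightMatrix(q=q))
        se = np.sqrt(1.5 / n)
        assert abs(prior.mean[0] - 2.0) < 3 * se + 0.1


class TestMStep:
    def test_zero_error_equals_naive_fit(self, logistic_data, quad_fitter):
        y, _, data = logistic_data
        spec = MeasurementErrorSpec(["w"], 0.0)
        naive = quad_fitter.fit(y, data)
        imps = draw_imputations(data, spec, B=6, seed=0)
        q = np.full((len(y), 6), 1.0 / 6)
        fit = m_step(y, imps, WeightMatrix(q=q), quad_fitter, data)
        np.testing.assert_allclose(fit.beta, naive.beta, atol=1e-8)

    def test_single_imputation_unit_weights_is_plain_fit(self, logistic_data,
                                                         quad_fitter, me_spec):
        y, _, data = logistic_data
        imps = draw_imputations(data, me_spec, B=1, seed=4)
        q = np.ones((len(y), 1))
        fit = m_step(y, imps, WeightMatrix(q=q), quad_fitter, data)
        imputed = data.copy()
        imputed["w"] = imps.values[0, :, 0]
        direct = quad_fitter.fit(y, imputed)
        np.testing.assert_allclose(fit.beta, direct.beta, atol=1e-10)

    def test_gaussian_m_step_matches_wls_closed_form(self, rng):
        """Stacked weighted fit equals (X'QX)^-1 X'Qy on a 5-point toy."""
        n, B = 5, 3
        w = rng.standard_normal(n)
        y = 1.0 + 2.0 * w + rng.standard_normal(n)
        data = pd.DataFrame({"w": w})
        spec = MeasurementErrorSpec(["w"], 0.3)
        f = GlmFitter("gaussian", ["w"])
        f.builder.freeze(data)
        imps = draw_imputations(data, spec, B=B, seed=2)
        q = rng.uniform(0.1, 1.0, (n, B))
        q /= q.sum(axis=1, keepdims=True)
        fit = m_step(y, imps, WeightMatrix(q=q), f, data)
        X = np.column_stack([np.ones(n * B),
                             imps.values[:, :, 0].reshape(-1)])
        Q = q.T.reshape(-1)
        yy = np.tile(y, B)
        wls = np.linalg.solve((X.T * Q) @ X, X.T @ (Q * yy))
        np.testing.assert_allclose(fit.beta, wls, atol=1e-10)


class TestEss:
    def test_uniform_row_gives_B(self):
        wts = WeightMatrix(q=np.full((4, 10), 0.1))
        ess, mean = effective_sample_size(wts)
        np.testing.assert_allclose(ess, 10.0)
        assert mean == pytest.approx(10.0)

    def test_degenerate_row_gives_one(self):
        q = np.zeros((1, 5))
        q[0, 2] = 1.0
        ess, _ = effective_sample_size(WeightMatrix(q=q))
        assert ess[0] == pytest.approx(1.0)

    def test_direct_formula(self):
        q = np.array([[0.5, 0.25, 0.25]])
        ess, _ = effective_sample_size(WeightMatrix(q=q))
        assert ess[0] == pytest.approx(1.0 / 0.375, abs=1e-12)

    def test_bounds(self, rng):
        q = rng.dirichlet(np.ones(8), size=40)
        ess, _ = effective_sample_size(WeightMatrix(q=q))
        assert np.all(ess >= 1.0 - 1e-12) and np.all(ess <= 8.0 + 1e-12)


class TestObservedLoglik:
    def test_zero_error_collapses_to_naive_plus_prior(self, logistic_data,
                                                      quad_fitter):
        y, _, data = logistic_data
        spec = MeasurementErrorSpec(["w"], 0.0)
        imps = draw_imputations(data, spec, B=4, seed=0)
        prior = initial_prior(data, spec)
        beta = quad_fitter.fit(y, data).beta
        ll = observed_loglik(y, imps, quad_fitter, prior, beta, data)
        naive_ll = float(np.sum(quad_fitter.loglik_i(y, data, beta)))
        fx = float(np.sum(prior.logpdf(data[["w"]].to_numpy())))
        assert ll == pytest.approx(naive_ll + fx, abs=1e-8)

    def test_matches_conjugate_gaussian_marginal(self, rng):
        """MC marginal vs the closed-form joint density of (y, w).

        Gaussian response y = beta*x + e with x ~ N(mu, s2x), w = x + u:
        (1/B) sum_b f_Y f_X estimates f(y,w) = N(y; b*m_xw, b^2 v + s2) *
        N(w; mu, s2x + s2u).
        """
        n, B = 40, 4000
        mu, s2x, s2u, s2, b = 1.0, 1.5, 0.5, 0.3, 0.8
        x = rng.normal(mu, np.sqrt(s2x), n)
        w = x + rng.normal(0, np.sqrt(s2u), n)
        y = b * x + rng.normal(0, np.sqrt(s2), n)
        data = pd.DataFrame({"w": w})
        f = GlmFitter("gaussian", ["w"], dispersion=s2, intercept=False)
        f.builder.freeze(data)
        spec = MeasurementErrorSpec(["w"], s2u)
        imps = draw_imputations(data, spec, B=B, seed=11)
        prior = PriorSpec(mean=[mu], cov=[[s2x]])
        ll = observed_loglik(y, imps, f, prior, np.array([b]), data)
        shrink = s2x / (s2x + s2u)
        m_xw = mu + shrink * (w - mu)
        v = s2x * s2u / (s2x + s2u)
        closed = (stats.norm.logpdf(y, b * m_xw, np.sqrt(b**2 * v + s2))
                  + stats.norm.logpdf(w, mu, np.sqrt(s2x + s2u))).sum()
        # 3x the Monte-Carlo standard error of the summed log estimate
        assert ll == pytest.approx(closed, abs=0.4)


class TestRunMcem:
    def test_em_ascent_on_fixed_imputations(self, logistic_data, quad_fitter,
                                            me_spec):
        y, _, data = logistic_data
        res = run_mcem(quad_fitter, y, data, me_spec, B=25, seed=3,
                       compute_se=False)
        diffs = np.diff(res.trace["loglik"].to_numpy())
        assert np.all(diffs > -1e-6)

    def test_zero_error_reduction(self, logistic_data):
        y, _, data = logistic_data
        f = GlmFitter("binomial", ["poly(w, 2)"])
        f.builder.freeze(data)
        naive = f.fit(y, data)
        from eivfit import naive_covariance

        _, naive_se = naive_covariance(f, y, data, naive.beta)
        spec0 = MeasurementErrorSpec(["w"], 0.0)
        res = run_mcem(f, y, data, spec0, B=10, seed=1)
        np.testing.assert_allclose(res.beta, naive.beta, atol=1e-8)
        np.testing.assert_allclose(res.se, naive_se, atol=1e-8)

    def test_seed_determinism(self, logistic_data, me_spec):
        y, _, data = logistic_data
        out = []
        for _ in range(2):
            f = GlmFitter("binomial", ["poly(w, 2)"])
            f.builder.freeze(data)
            out.append(run_mcem(f, y, data, me_spec, B=15, seed=77))
        np.testing.assert_array_equal(out[0].beta, out[1].beta)
        np.testing.assert_array_equal(out[0].se, out[1].se)
        np.testing.assert_array_equal(out[0].weights.q, out[1].weights.q)
        assert out[0].loglik_obs == out[1].loglik_obs

    def test_corrects_attenuation_toward_truth(self, logistic_data, me_spec):
        y, x, data = logistic_data
        f = GlmFitter("binomial", ["poly(w, 2)"])
        f.builder.freeze(data)
        naive = f.fit(y, data)
        res = run_mcem(f, y, data, me_spec, B=30, seed=2)
        # the quadratic coefficient is attenuated toward zero by the noise;
        # the corrected estimate should move back toward -0.3
        assert abs(res.beta[2] - (-0.3)) < abs(naive.beta[2] - (-0.3))

    def test_nonconvergence_flagged_with_warning(self, logistic_data, me_spec):
        y, _, data = logistic_data
        f = GlmFitter("binomial", ["poly(w, 2)"])
        f.builder.freeze(data)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = run_mcem(f, y, data, me_spec, B=15, seed=1, max_iter=2,
                           compute_se=False)
        assert not res.converged
        assert res.n_iter == 2
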