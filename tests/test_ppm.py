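import numpy as np
import pandas as pd
import pytest

from eivfit import (
    MeasurementErrorSpec,
    PointPattern,
    build_berman_turner,
    fit_ppm,
    predict_intensity,
    reliability_ratio,
)
from eivfit.ppm import ppm_fitter, ppm_loglik


def _grid_raster(window, res, cov_fns=None):
    x0, x1, y0, y1 = window
    xs = np.arange(x0 + res / 2, x1, res)
    ys = np.arange(y0 + res / 2, y1, res)
    gx, gy = np.meshgrid(xs, ys)
    out = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel()})
    for name, fn in (cov_fns or {}).items():
        out[name] = fn(out["x"].to_numpy(), out["y"].to_numpy())
    return out


class TestQuadrature:
    def test_unit_square_weights_sum_to_area(self):
        pat = PointPattern([[0.5, 0.5]], (0, 1, 0, 1))
        scheme = build_berman_turner(pat, grid_resolution=0.1)
        assert scheme.n_quad == 100
        quad_w = scheme.weights[~scheme.is_presence]
        np.testing.assert_allclose(quad_w, 0.01, atol=1e-15)
        assert quad_w.sum() == pytest.approx(1.0, rel=1e-6)

    def test_pseudo_responses_are_inverse_weights(self):
        pat = PointPattern([[0.2, 0.2], [0.4, 0.9], [0.8, 0.1]], (0, 1, 0, 1))
        scheme = build_berman_turner(pat, grid_resolution=0.25)
        np.testing.assert_allclose(scheme.pseudo_response[:3], 1e6)
        np.testing.assert_allclose(scheme.pseudo_response[3:], 0.0)
        np.testing.assert_allclose(
            scheme.weights * scheme.pseudo_response,
            np.concatenate([np.ones(3), np.zeros(scheme.n_quad)]))

    def test_weighted_poisson_equals_direct_pp_loglik(self, rng):
        """Both displayed forms of the Berman-Turner objective agree.

        On a toy scheme, sum_j w_j{y_j log lam - lam} equals
        sum_i log lam(s_i) - sum_j w_j lam(s_j) up to the presence-point
        epsilon terms, at any coefficient value.
        """
        raster = _grid_raster((0, 1, 0, 1), 0.5,
                              {"t": lambda x, y: x + 0.2 * y})
        pat = PointPattern([[0.3, 0.6]], (0, 1, 0, 1))
        scheme = build_berman_turner(pat, raster)
        f = ppm_fitter(["t"])
        f.builder.freeze(scheme.data)
        for beta in ([0.0, 0.0], [0.5, -1.0], [-1.0, 2.0]):
            beta = np.asarray(beta, dtype=float)
            weighted = float(np.sum(
                scheme.weights * (scheme.pseudo_response *
                                  f.predict(scheme.data, beta)
                                  - np.exp(f.predict(scheme.data, beta)))))
            direct = ppm_loglik(scheme, f, beta)
            # they differ only by eps*lam at the single presence point
            assert weighted == pytest.approx(direct, abs=1e-4)

    def test_presence_outside_raster_rejected(self):
        raster = _grid_raster((0, 1, 0, 1), 0.25, {"t": lambda x, y: x})
        pat = PointPattern([[0.5, 0.5], [4.0, 4.0]], (0, 5, 0, 5))
        with pytest.raises(ValueError, match="outside raster"):
            build_berman_turner(pat, raster)


class TestFit:
    def test_homogeneous_intensity_closed_form(self, rng):
        """Constant intensity: lambda_hat = m / |A| to 1e-8."""
        m, side = 60, 100.0
        pat = PointPattern(rng.uniform(0, side, (m, 2)), (0, side, 0, side))
        scheme = build_berman_turner(pat, grid_resolution=5.0)
        _, fit = fit_ppm(scheme, [])
        lam = float(np.exp(fit.beta[0]))
        assert lam == pytest.approx(m / side**2, abs=1e-8)

    def test_inhomogeneous_recovery_within_3se(self, rng):
        """log lam = 1 + 0.8 x(s) recovered from a thinned simulation."""
        side = 10.0
        window = (0, side, 0, side)
        raster = _grid_raster(window, 0.25,
                              {"t": lambda x, y: (x - side / 2) / side})
        b0, b1 = 1.0, 0.8
        lam = np.exp(b0 + b1 * raster["t"].to_numpy())
        cell = 0.25**2
        counts = rng.poisson(lam * cell)
        pts = []
        for (px, py), c in zip(raster[["x", "y"]].to_numpy(), counts):
            for _ in range(c):
                pts.append([px + rng.uniform(-0.125, 0.125),
                            py + rng.uniform(-0.125, 0.125)])
        pat = PointPattern(np.array(pts), window)
        scheme = build_berman_turner(pat, raster)
        fitter, fit = fit_ppm(scheme, ["t"])
        from eivfit import naive_covariance

        _, se = naive_covariance(fitter, scheme.pseudo_response, scheme.data,
                                 fit.beta)
        assert abs(fit.beta[1] - b1) < 3 * se[1]

    def test_mcem_reduces_attenuation_bias(self, rng):
        """With a noisy covariate, the corrected slope beats the naive one."""
        side = 10.0
        window = (0, side, 0, side)
        clean = _grid_raster(window, 0.5, {"t": lambda x, y: np.zeros_like(x)})
        b0, b1, s2u = 0.5, 1.0, 0.4
        biases_naive, biases_mcem = [], []
        for rep in range(8):
            rr = np.random.default_rng([17, rep])
            t_true = rr.normal(0, 1, len(clean))
            raster = clean.copy()
            raster["t"] = t_true + rr.normal(0, np.sqrt(s2u), len(clean))
            lam = np.exp(b0 + b1 * t_true)
            counts = rr.poisson(lam * 0.25)
            idx = np.repeat(np.arange(len(clean)), counts)
            if len(idx) < 5:
                continue
            pts = raster[["x", "y"]].to_numpy()[idx] + \
                rr.uniform(-0.25, 0.25, (len(idx), 2))
            pts = np.clip(pts, 1e-6, side - 1e-6)
            pat = PointPattern(pts, window)
            scheme = build_berman_turner(pat, raster)
            _, naive = fit_ppm(scheme, ["t"])
            _, mcem = fit_ppm(scheme, ["t"],
                              me_spec=MeasurementErrorSpec(["t"], s2u),
                              B=25, seed=rep, compute_se=False)
            biases_naive.append(naive.beta[1] - b1)
            biases_mcem.append(mcem.beta[1] - b1)
        assert abs(np.mean(biases_mcem)) < abs(np.mean(biases_naive))


class TestPredictIntensity:
    @pytest.fixture
    def fitted(self, rng):
        window = (0, 10, 0, 10)
        raster = _grid_raster(window, 0.5, {"temp": lambda x, y: y / 10.0})
        pat = PointPattern(rng.uniform(0, 10, (40, 2)), window)
        scheme = build_berman_turner(pat, raster)
        fitter, fit = fit_ppm(scheme, ["poly(temp, 2)"])
        return fitter, fit, raster

    def test_zero_shift_reproduces_fit(self, fitted):
        fitter, fit, raster = fitted
        base = predict_intensity(fitter, fit.beta, raster)
        shifted = predict_intensity(fitter, fit.beta, raster, {"temp": 0.0})
        np.testing.assert_allclose(shifted["intensity"], base["intensity"])

    def test_intercept_only_model_ignores_any_shift(self, rng):
        window = (0, 10, 0, 10)
        raster = _grid_raster(window, 1.0, {"temp": lambda x, y: y})
        pat = PointPattern(rng.uniform(0, 10, (20, 2)), window)
        scheme = build_berman_turner(pat, raster[["x", "y"]])
        fitter, fit = fit_ppm(scheme, [])
        with pytest.raises(ValueError, match="not a model covariate"):
            predict_intensity(fitter, fit.beta, raster, {"temp": 1.0})

    def test_warming_shift_moves_intensity_along_gradient(self, rng):
        """A +shift on a north-south temperature gradient moves the
        intensity-weighted mean location monotonically."""
        window = (0, 10, 0, 10)
        raster = _grid_raster(window, 0.5, {"temp": lambda x, y: 20 + y})
        # species prefers temp ~ 25: quadratic peak at mid-window
        lam = np.exp(-0.5 * (raster["temp"] - 25) ** 2 / 4)
        rr = np.random.default_rng(3)
        counts = rr.poisson(lam * 2.0)
        idx = np.repeat(np.arange(len(raster)), counts)
        pts = raster[["x", "y"]].to_numpy()[idx]
        pat = PointPattern(np.clip(pts, 0, 10 - 1e-9), window)
        scheme = build_berman_turner(pat, raster)
        fitter, fit = fit_ppm(scheme, ["poly(temp, 2)"])
        centroids = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            pred = predict_intensity(fitter, fit.beta, raster, {"temp": shift})
            lam_hat = pred["intensity"].to_numpy()
            centroids.append(float(np.sum(lam_hat * pred["y"]) / lam_hat.sum()))
        diffs = np.diff(centroids)
        # warming pushes the preferred zone toward cooler (lower-y) cells
        assert np.all(diffs < 0)


def test_reliability_ratio_bookkeeping(rng):
    """Declared error variance reproduces RR = 100(1 - s2u/s2w)."""
    t = rng.normal(0, 1, 4000)
    w = t + rng.normal(0, 0.5, 4000)
    rr = reliability_ratio(0.25, float(np.var(w)))
    assert rr == pytest.approx(100 * (1 - 0.25 / np.var(w)))
    assert 75 < rr < 85
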