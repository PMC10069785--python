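"""Weighted maximum / penalised likelihood fitters.

Every fitter here satisfies one contract: it estimates coefficients from
responses ``y``, raw covariate data and non-negative observation weights
``q`` by maximising ``sum_i q_i * loglik_i(beta)`` (minus a quadratic spline
penalty where applicable), and it exposes per-observation log-likelihood,
score and Jacobian evaluations.  That is all the MCEM wrapper needs: the
E-step reweights imputed data, the M-step calls ``fit`` on stacked data, and
the Louis information is assembled from the scores and Jacobians.

Fitters:

* :class:`GlmFitter` -- exponential-family GLMs (gaussian-identity,
  binomial-logit, poisson-log), backed by statsmodels IRLS with frequency
  weights.
* :class:`GamFitter` -- penalised B-spline GAMs fitted by penalised IRLS
  with difference penalties, smoothing parameters chosen by GCV.
* :class:`PosBinomialFitter` -- zero-truncated (positive) binomial
  conditional likelihood for closed-population capture--recapture.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .families import Family, get_family
from .terms import DesignBuilder, SplineTerm
from .types import FitResult

__all__ = [
    "FitError",
    "GlmFitter",
    "GamFitter",
    "PosBinomialFitter",
    "fit_weighted_glm",
    "fit_weighted_gam",
    "fit_weighted_posbinomial",
]


class FitError(RuntimeError):
    """Raised when a weighted fit cannot be completed."""


def _effective_weights(n, weights, base):
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise FitError("observation weights must be non-negative")
    if not np.any(w > 0):
        raise FitError("observation weights are all zero")
    if base is not None:
        w = w * base
    return w


class _BaseFitter:
    """Shared design handling for design-matrix based fitters."""

    def __init__(self, family, terms, base_weight_col: str | None = None,
                 intercept: bool = True):
        self.family: Family = get_family(family)
        self.builder = DesignBuilder(terms, intercept=intercept)
        self.base_weight_col = base_weight_col
        self.dispersion_: float = 1.0

    # -- plumbing ----------------------------------------------------------
    def _base_weights(self, data: pd.DataFrame):
        if self.base_weight_col is None:
            return None
        return data[self.base_weight_col].to_numpy(dtype=float)

    def design(self, data: pd.DataFrame):
        return self.builder.build(data)

    @property
    def param_names(self):
        return list(self.builder.column_names)

    def required_columns(self):
        cols = list(self.builder.covariate_names())
        if self.base_weight_col:
            cols.append(self.base_weight_col)
        return cols

    def predict(self, data: pd.DataFrame, beta: np.ndarray) -> np.ndarray:
        """Linear predictor at ``beta`` (offset included)."""
        X, offset = self.design(data)
        return X @ np.asarray(beta, dtype=float) + offset

    # -- per-observation quantities (base weights applied) -----------------
    def loglik_i(self, y, data, beta, dispersion=None):
        disp = self.dispersion_ if dispersion is None else dispersion
        eta = self.predict(data, beta)
        ll = self.family.loglik_i(np.asarray(y, dtype=float), eta, disp)
        base = self._base_weights(data)
        return ll if base is None else base * ll

    def score_i(self, y, data, beta, dispersion=None):
        """Per-observation score vectors, shape (n, d)."""
        disp = self.dispersion_ if dispersion is None else dispersion
        X, offset = self.design(data)
        eta = X @ np.asarray(beta, dtype=float) + offset
        g = self.family.dl_deta(np.asarray(y, dtype=float), eta, disp)
        base = self._base_weights(data)
        if base is not None:
            g = g * base
        return g[:, None] * X

    def jacobian_i(self, y, data, beta, dispersion=None):
        """Per-observation Jacobians d2l/dbeta2, shape (n, d, d)."""
        disp = self.dispersion_ if dispersion is None else dispersion
        X, offset = self.design(data)
        eta = X @ np.asarray(beta, dtype=float) + offset
        h = self.family.d2l_deta2(np.asarray(y, dtype=float), eta, disp)
        base = self._base_weights(data)
        if base is not None:
            h = h * base
        return h[:, None, None] * X[:, None, :] * X[:, :, None]

    def penalty_matrix(self):
        """Quadratic penalty (lambda * S) or None for unpenalised fitters."""
        return None

    def _update_dispersion(self, y, eta, w, d):
        if self.family.has_dispersion and self._estimate_dispersion:
            resid2 = (np.asarray(y, dtype=float) - eta) ** 2
            denom = max(w.sum() - d, 1.0)
            self.dispersion_ = float(np.sum(w * resid2) / denom)


class GlmFitter(_BaseFitter):
    """Weighted exponential-family GLM via IRLS (statsmodels backend).

    Maximises ``sum_i q_i loglik_i`` where ``q`` are prior observation
    weights, distinct from binomial trial counts.  With unit weights this is
    the ordinary (naive) maximum-likelihood fit.

    Parameters
    ----------
    family : {"gaussian", "binomial", "poisson"} or Family
    terms : list of term strings / Term objects
    dispersion : float, optional
        Fix the gaussian dispersion; by default it is estimated by the
        weighted Pearson statistic at each fit.
    base_weight_col : str, optional
        Name of a data column of fixed per-row likelihood weights (used by
        the point-process quadrature, where each row carries a Berman--Turner
        weight).  These multiply the MCEM weights.
    """

    def __init__(self, family, terms, dispersion: float | None = None,
                 base_weight_col: str | None = None, intercept: bool = True):
        super().__init__(family, terms, base_weight_col, intercept)
        self._estimate_dispersion = dispersion is None
        if dispersion is not None:
            self.dispersion_ = float(dispersion)

    def fit(self, y, data: pd.DataFrame, weights=None,
            start: np.ndarray | None = None) -> FitResult:
        y = np.asarray(y, dtype=float)
        X, offset = self.design(data)
        w = _effective_weights(len(y), weights, self._base_weights(data))
        if np.linalg.matrix_rank(X[w > 0]) < X.shape[1]:
            raise FitError(
                "design matrix is rank deficient on the weighted support"
            )
        model = sm.GLM(
            y, X, family=self.family.statsmodels_family(),
            offset=offset if np.any(offset) else None, freq_weights=w,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(start_params=start, maxiter=200, tol=1e-10)
            except Exception as exc:  # perfect separation, singular weights...
                raise FitError(f"GLM fit failed: {exc}") from exc
        beta = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(beta)):
            raise FitError("GLM fit returned non-finite coefficients")
        eta = X @ beta + offset
        self._update_dispersion(y, eta, w, X.shape[1])
        ll = float(np.sum(w * self.family.loglik_i(y, eta, self.dispersion_)))
        return FitResult(
            beta=beta, linear_predictor=eta, loglik=ll,
            converged=bool(getattr(res, "converged", True)),
            edf=float(X.shape[1]), dispersion=self.dispersion_,
        )


class GamFitter(_BaseFitter):
    """Penalised-spline GAM via penalised IRLS.

    Smooth terms ``s(x, k=...)`` use cubic B-spline bases with quantile
    knots (frozen from the first data seen) and an order-2 difference
    penalty; smoothing parameters are selected by generalised
    cross-validation, either refreshed on every weighted fit
    (``select_lambda="gcv"``, the default, so each EM M-step re-selects) or
    frozen at user-supplied values (``select_lambda="fixed"``).
    """

    _LAMBDA_GRID = np.logspace(-3.0, 8.0, 12)

    def __init__(self, family, terms, select_lambda: str = "gcv",
                 lambdas: dict | None = None, dispersion: float | None = None,
                 base_weight_col: str | None = None, intercept: bool = True):
        super().__init__(family, terms, base_weight_col, intercept)
        if select_lambda not in ("gcv", "fixed"):
            raise ValueError("select_lambda must be 'gcv' or 'fixed'")
        self.select_lambda = select_lambda
        self._user_lambdas = dict(lambdas or {})
        self._estimate_dispersion = dispersion is None
        if dispersion is not None:
            self.dispersion_ = float(dispersion)
        if not any(isinstance(t, SplineTerm) for t in self.builder.terms):
            raise ValueError("GamFitter requires at least one spline term")

    # penalised IRLS core ---------------------------------------------------
    def _pirls(self, y, X, offset, w, S, start=None, maxiter=200, tol=1e-10):
        d = X.shape[1]
        beta = np.zeros(d) if start is None else np.asarray(start, dtype=float)
        last = -np.inf
        for it in range(maxiter):
            eta = X @ beta + offset
            g = self.family.dl_deta(y, eta)
            h = -self.family.d2l_deta2(y, eta)
            h = np.maximum(h, 1e-10)
            W = w * h
            z = eta - offset + g / h
            A = (X.T * W) @ X + S
            b = (X.T * W) @ z
            try:
                beta_new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"penalised IRLS normal equations singular: {exc}")
            pen_ll = self._penalised_loglik(y, X, offset, w, S, beta_new)
            # step-halving keeps the penalised likelihood non-decreasing
            step = beta_new - beta
            n_halve = 0
            while pen_ll < last - 1e-12 and n_halve < 30:
                step *= 0.5
                beta_new = beta + step
                pen_ll = self._penalised_loglik(y, X, offset, w, S, beta_new)
                n_halve += 1
            beta = beta_new
            if abs(pen_ll - last) < tol * (abs(pen_ll) + 1.0):
                return beta, True, it + 1
            last = pen_ll
        return beta, False, maxiter

    def _penalised_loglik(self, y, X, offset, w, S, beta):
        eta = X @ beta + offset
        return float(np.sum(w * self.family.loglik_i(y, eta)) -
                     0.5 * beta @ S @ beta)

    def _edf(self, X, offset, w, S, beta, y):
        eta = X @ beta + offset
        h = np.maximum(-self.family.d2l_deta2(y, eta), 1e-10)
        W = w * h
        XtWX = (X.T * W) @ X
        return float(np.trace(np.linalg.solve(XtWX + S, XtWX)))

    def _gcv(self, y, X, offset, w, S, beta):
        eta = X @ beta + offset
        dev = float(np.sum(w * self.family.deviance_i(y, eta)))
        n_eff = float(np.sum(w))
        edf = self._edf(X, offset, w, S, beta, y)
        denom = max(n_eff - edf, 1e-8)
        return n_eff * dev / denom**2, edf

    def fit(self, y, data: pd.DataFrame, weights=None,
            start: np.ndarray | None = None) -> FitResult:
        y = np.asarray(y, dtype=float)
        X, offset = self.design(data)
        w = _effective_weights(len(y), weights, self._base_weights(data))
        for name, lam in self._user_lambdas.items():
            self.builder.spline_info[name].lam = float(lam)
        if self.select_lambda == "gcv":
            self._select_by_gcv(y, X, offset, w, start)
        S = self.builder.penalty_matrix()
        beta, conv, _ = self._pirls(y, X, offset, w, S, start=start)
        _, edf = self._gcv(y, X, offset, w, S, beta)
        eta = X @ beta + offset
        self._update_dispersion(y, eta, w, edf)
        ll = float(np.sum(w * self.family.loglik_i(y, eta, self.dispersion_)))
        return FitResult(beta=beta, linear_predictor=eta, loglik=ll,
                         converged=conv, edf=edf, dispersion=self.dispersion_,
                         extra={"lambdas": {n: i.lam for n, i in
                                            self.builder.spline_info.items()}})

    def _select_by_gcv(self, y, X, offset, w, start):
        """Coordinate-wise GCV grid search over spline smoothing parameters."""
        names = list(self.builder.spline_info)
        n_sweeps = 1 if len(names) == 1 else 2
        for _ in range(n_sweeps):
            for name in names:
                info = self.builder.spline_info[name]
                best = (np.inf, info.lam)
                for lam in self._LAMBDA_GRID:
                    info.lam = float(lam)
                    S = self.builder.penalty_matrix()
                    try:
                        beta, _, _ = self._pirls(y, X, offset, w, S,
                                                 start=start, maxiter=50)
                    except FitError:
                        continue
                    score, _ = self._gcv(y, X, offset, w, S, beta)
                    if score < best[0]:
                        best = (score, float(lam))
                info.lam = best[1]

    def penalty_matrix(self):
        return self.builder.penalty_matrix()


class PosBinomialFitter(_BaseFitter):
    """Zero-truncated binomial conditional likelihood (capture--recapture).

    Individuals enter the data only if captured at least once across ``tau``
    occasions; with per-individual constant capture probability
    ``p_i = logistic(eta_i)`` the conditional log-likelihood contribution is

        l_i = c_i log p_i + (tau - c_i) log(1 - p_i) - log pi_i + const,

    where ``c_i`` is the capture count and ``pi_i = 1 - (1 - p_i)^tau`` the
    inclusion probability.  Fitted by weighted penalised Newton iterations
    with analytic gradient and Hessian.
    """

    def __init__(self, tau: int, terms, lambdas: dict | None = None,
                 intercept: bool = True):
        super().__init__("binomial", terms, None, intercept)
        if tau < 2:
            raise ValueError("need at least two capture occasions (tau >= 2)")
        self.tau = int(tau)
        # spline info exists only after freeze; stash lambdas for fit time
        self._user_lambdas = dict(lambdas or {})

    # -- conditional-likelihood pieces --------------------------------------
    def _p_pi(self, eta):
        p = 1.0 / (1.0 + np.exp(-eta))
        log_s = self.tau * np.log1p(-np.clip(p, None, 1 - 1e-12))
        surv = np.exp(log_s)              # (1-p)^tau
        pi = -np.expm1(log_s)             # 1 - (1-p)^tau
        return p, surv, np.clip(pi, 1e-12, 1.0)

    def inclusion_prob(self, eta):
        """pi_i = 1 - (1 - p_i)^tau at the given linear predictor."""
        return self._p_pi(np.asarray(eta, dtype=float))[2]

    def loglik_i(self, y, data, beta, dispersion=None):
        c = np.asarray(y, dtype=float)
        eta = self.predict(data, beta)
        p, _, pi = self._p_pi(eta)
        from scipy.special import gammaln
        const = (gammaln(self.tau + 1) - gammaln(c + 1)
                 - gammaln(self.tau - c + 1))
        return (c * np.log(p) + (self.tau - c) * np.log1p(-p)
                - np.log(pi) + const)

    def _dl_deta(self, c, eta):
        p, surv, pi = self._p_pi(eta)
        return c * (1 - p) - (self.tau - c) * p - self.tau * p * surv / pi

    def _d2l_deta2(self, c, eta):
        tau = self.tau
        p, surv, pi = self._p_pi(eta)
        base = -tau * p * (1 - p)
        dg = -tau * p * surv * (((1 - p) - tau * p) * pi - tau * p * surv) / pi**2
        return base + dg

    def score_i(self, y, data, beta, dispersion=None):
        X, offset = self.design(data)
        eta = X @ np.asarray(beta, dtype=float) + offset
        g = self._dl_deta(np.asarray(y, dtype=float), eta)
        return g[:, None] * X

    def jacobian_i(self, y, data, beta, dispersion=None):
        X, offset = self.design(data)
        eta = X @ np.asarray(beta, dtype=float) + offset
        h = self._d2l_deta2(np.asarray(y, dtype=float), eta)
        return h[:, None, None] * X[:, None, :] * X[:, :, None]

    def fit(self, y, data: pd.DataFrame, weights=None,
            start: np.ndarray | None = None) -> FitResult:
        c = np.asarray(y, dtype=float)
        if np.any(c < 1):
            raise FitError(
                "capture count of zero found: conditional likelihood requires "
                "every individual to be captured at least once"
            )
        X, offset = self.design(data)
        w = _effective_weights(len(c), weights, None)
        for name, lam in self._user_lambdas.items():
            if name in self.builder.spline_info:
                self.builder.spline_info[name].lam = float(lam)
        S = self.builder.penalty_matrix() if self.builder.has_splines else \
            np.zeros((X.shape[1], X.shape[1]))

        beta = np.zeros(X.shape[1]) if start is None else np.array(start, float)
        if start is None and self.builder.intercept:
            pbar = np.clip(np.sum(w * c) / (np.sum(w) * self.tau), 1e-3, 1 - 1e-3)
            beta[0] = np.log(pbar / (1 - pbar))

        def pen_ll(b):
            eta = X @ b + offset
            p, _, pi = self._p_pi(eta)
            ll = c * np.log(p) + (self.tau - c) * np.log1p(-p) - np.log(pi)
            return float(np.sum(w * ll) - 0.5 * b @ S @ b)

        last = pen_ll(beta)
        converged = False
        for it in range(200):
            eta = X @ beta + offset
            g = self._dl_deta(c, eta)
            h = self._d2l_deta2(c, eta)
            grad = X.T @ (w * g) - S @ beta
            H = -(X.T * (w * h)) @ X + S
            H += 1e-10 * np.eye(H.shape[0])
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"singular Hessian in positive-binomial fit: {exc}")
            new = pen_ll(beta + step)
            n_halve = 0
            while (not np.isfinite(new) or new < last - 1e-12) and n_halve < 40:
                step *= 0.5
                new = pen_ll(beta + step)
                n_halve += 1
            beta = beta + step
            if abs(new - last) < 1e-11 * (abs(new) + 1.0):
                converged = True
                last = new
                break
            last = new
        eta = X @ beta + offset
        edf = X.shape[1] if not self.builder.has_splines else self._pb_edf(X, w, c, eta, S)
        ll = float(np.sum(w * self.loglik_i(c, data, beta)))
        return FitResult(beta=beta, linear_predictor=eta, loglik=ll,
                         converged=converged, edf=float(edf))

    def _pb_edf(self, X, w, c, eta, S):
        h = -self._d2l_deta2(c, eta)
        h = np.maximum(h, 1e-10)
        XtWX = (X.T * (w * h)) @ X
        return float(np.trace(np.linalg.solve(XtWX + S, XtWX)))

    def penalty_matrix(self):
        if self.builder.has_splines:
            return self.builder.penalty_matrix()
        return None


# -- functional wrappers (one call per fit, no state) ------------------------

def fit_weighted_glm(y, data, weights, family, terms, **kw) -> FitResult:
    """One-shot weighted GLM fit; see :class:`GlmFitter`."""
    f = GlmFitter(family, terms, **kw)
    f.builder.freeze(data)
    return f.fit(y, data, weights)


def fit_weighted_gam(y, data, weights, family, terms, **kw) -> FitResult:
    """One-shot weighted penalised-spline GAM fit; see :class:`GamFitter`."""
    f = GamFitter(family, terms, **kw)
    f.builder.freeze(data)
    return f.fit(y, data, weights)


def fit_weighted_posbinomial(histories, covariate, weights=None, terms=("x",),
                             covariate_name: str = "x", **kw) -> FitResult:
    """One-shot weighted positive-binomial conditional-likelihood fit.

    ``histories`` is an n x tau 0/1 capture-history matrix; rows are reduced
    to capture counts (the sufficient statistic under occasion-constant
    capture probabilities).
    """
    H = np.asarray(histories)
    if H.ndim != 2 or H.shape[1] < 2:
        raise ValueError("histories must be an n x tau matrix with tau >= 2")
    c = H.sum(axis=1)
    data = pd.DataFrame({covariate_name: np.asarray(covariate, dtype=float)})
    f = PosBinomialFitter(H.shape[1], terms, **kw)
    f.builder.freeze(data)
    return f.fit(c, data, weights)
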