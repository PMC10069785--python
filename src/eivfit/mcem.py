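"""Iteratively reweighted Monte Carlo EM for covariate measurement error.

The observed covariate is ``W = X + U`` with ``U ~ N(0, Sigma_u)`` known and
a multivariate-normal structural prior ``f_X`` on the latent covariate.  The
algorithm:

1. Fit the naive model on the contaminated data -> initial coefficients.
2. Draw ``B`` fixed imputations ``x~(b) = w - u~(b)`` with ``u~(b)`` sampled
   from the error distribution (prior proposals; never redrawn).
3. E-step: update importance weights
   ``q_i(b) propto f_Y(y_i | x~_i(b); beta) f_X(x~_i(b))``,
   normalised over ``b`` for each observation.
4. M-step: refit the model on the ``nB`` stacked imputed rows with
   observation weights ``q`` -- any weighted maximum / penalised likelihood
   fitter can be used unchanged.
5. Repeat E/M until the coefficients stop moving; conditional on the fixed
   imputations this is an exact EM, so the Monte-Carlo observed
   log-likelihood ascends.

Standard errors come from the Louis observed information assembled in
:mod:`eivfit.inference`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .types import (
    ImputationSet,
    MCEMResult,
    MeasurementErrorSpec,
    PriorSpec,
    WeightMatrix,
)

__all__ = [
    "draw_imputations",
    "stack_imputed_data",
    "compute_importance_weights",
    "update_prior",
    "initial_prior",
    "m_step",
    "effective_sample_size",
    "observed_loglik",
    "run_mcem",
]


def draw_imputations(w, spec: MeasurementErrorSpec, B: int, seed: int) -> ImputationSet:
    """Draw ``B`` fixed Monte-Carlo imputations ``x~(b) = w - u~(b)``.

    ``w`` may be the full data frame (the contaminated columns are taken
    from ``spec``) or an (n, p) array of contaminated covariate values.
    Only contaminated covariates are ever touched.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if isinstance(w, pd.DataFrame):
        w_arr = w.loc[:, list(spec.columns)].to_numpy(dtype=float)
    else:
        w_arr = np.atleast_2d(np.asarray(w, dtype=float))
        if w_arr.shape[1] != spec.p and w_arr.shape[0] == spec.p:
            w_arr = w_arr.T
    if not np.all(np.isfinite(w_arr)):
        raise ValueError("contaminated covariates contain non-finite values")
    n, p = w_arr.shape
    rng = np.random.default_rng(seed)
    if spec.is_error_free:
        draws = np.zeros((B, n, p))
    else:
        draws = rng.multivariate_normal(
            np.zeros(p), spec.sigma_u, size=(B, n), method="cholesky"
        )
    values = w_arr[None, :, :] - draws
    return ImputationSet(values=values, draws=draws, seed=int(seed),
                         columns=spec.columns)


def stack_imputed_data(data: pd.DataFrame, imps: ImputationSet) -> pd.DataFrame:
    """Stack ``B`` copies of the data, contaminated columns imputed.

    Rows are ordered replicate-major: rows ``[b*n, (b+1)*n)`` hold imputation
    ``b``, so per-observation arrays reshape as ``(B, n)``.
    """
    B, n, _ = imps.values.shape
    stacked = pd.concat([data] * B, ignore_index=True)
    for j, col in enumerate(imps.columns):
        stacked[col] = imps.values[:, :, j].reshape(B * n)
    return stacked


def _log_fy_matrix(y, data, imps, fitter, beta, stacked=None) -> np.ndarray:
    """Per-observation response log-density at each imputation, shape (n, B)."""
    B, n, _ = imps.values.shape
    if stacked is None:
        stacked = stack_imputed_data(data, imps)
    y_rep = np.tile(np.asarray(y, dtype=float), B)
    ll = fitter.loglik_i(y_rep, stacked, beta)
    return np.asarray(ll, dtype=float).reshape(B, n).T


def _log_fx_matrix(imps: ImputationSet, prior: PriorSpec) -> np.ndarray:
    """Structural-prior log-density of each imputation, shape (n, B)."""
    return prior.logpdf(imps.values).T


def _normalise_rows(logw: np.ndarray) -> WeightMatrix:
    """Row-normalise on the log scale with per-row max subtraction."""
    if np.any(np.all(~np.isfinite(logw), axis=1)):
        bad = int(np.where(np.all(~np.isfinite(logw), axis=1))[0][0])
        raise FloatingPointError(
            f"importance weights underflowed for every imputation of "
            f"observation {bad}; increase B or check that sigma_u is plausible"
        )
    shifted = logw - logw.max(axis=1, keepdims=True)
    q = np.exp(shifted)
    q /= q.sum(axis=1, keepdims=True)
    return WeightMatrix(q=q)


def compute_importance_weights(y, imps: ImputationSet, fitter, prior: PriorSpec,
                               beta, data: pd.DataFrame,
                               stacked: pd.DataFrame | None = None,
                               groups=None) -> WeightMatrix:
    """Importance weights ``q_i(b) propto f_Y(y_i|x~_i(b); beta) f_X(x~_i(b))``.

    Normalised over imputations separately for each observation, computed on
    the log scale.  The proposal density ``f_U`` cancels because the
    imputations were drawn from it.  With ``groups``, rows of a group form
    one observational unit sharing one latent covariate value: their
    log-contributions are summed before normalisation and every row of the
    group carries the group's weight.
    """
    logw = _grouped_logweights(y, imps, fitter, prior, beta, data, stacked,
                               groups)
    q_group = _normalise_rows(logw).q
    if groups is None:
        return WeightMatrix(q=q_group)
    idx, _ = _group_index(groups, len(np.asarray(y)))
    return WeightMatrix(q=q_group[idx])


def _grouped_logweights(y, imps, fitter, prior, beta, data, stacked=None,
                        groups=None) -> np.ndarray:
    """Unnormalised log importance weights per observational unit (G, B)."""
    logw_rows = _log_fy_matrix(y, data, imps, fitter, beta, stacked)
    idx, G = _group_index(groups, logw_rows.shape[0])
    _, rep = np.unique(idx, return_index=True)
    logfx = prior.logpdf(imps.values[:, rep, :]).T       # (G, B)
    return _reduce_rows(logw_rows, idx, G) + logfx


def initial_prior(data: pd.DataFrame, spec: MeasurementErrorSpec,
                  groups=None) -> PriorSpec:
    """Moment-corrected starting prior: mean(w), cov(w) - Sigma_u (floored).

    With ``groups``, moments are taken over one representative row per group
    (rows in a group share the same contaminated measurement).
    """
    w = data.loc[:, list(spec.columns)].to_numpy(dtype=float)
    if groups is not None:
        idx, _ = _group_index(groups, len(w))
        _, rep = np.unique(idx, return_index=True)
        w = w[rep]
    mean = w.mean(axis=0)
    cov = np.atleast_2d(np.cov(w, rowvar=False)) - spec.sigma_u
    return PriorSpec(mean=mean, cov=cov)


def _group_index(groups, n: int) -> tuple[np.ndarray, int]:
    """Contiguous 0..G-1 group labels (identity when groups is None)."""
    if groups is None:
        return np.arange(n), n
    _, idx = np.unique(np.asarray(groups), return_inverse=True)
    return idx, int(idx.max()) + 1


def _reduce_rows(mat: np.ndarray, idx: np.ndarray, G: int) -> np.ndarray:
    """Sum rows of ``mat`` (first axis) within groups."""
    if G == mat.shape[0] and np.array_equal(idx, np.arange(G)):
        return np.asarray(mat, dtype=float)
    out = np.zeros((G,) + mat.shape[1:], dtype=float)
    np.add.at(out, idx, mat)
    return out


def _draw_grouped_imputations(data: pd.DataFrame, spec: MeasurementErrorSpec,
                              B: int, seed: int, idx: np.ndarray, G: int
                              ) -> ImputationSet:
    """One error draw per group and replicate, shared by the group's rows."""
    w_rows = data.loc[:, list(spec.columns)].to_numpy(dtype=float)
    p = spec.p
    rng = np.random.default_rng(seed)
    if spec.is_error_free:
        draws_g = np.zeros((B, G, p))
    else:
        draws_g = rng.multivariate_normal(
            np.zeros(p), spec.sigma_u, size=(B, G), method="cholesky"
        )
    draws_rows = draws_g[:, idx, :]
    values = w_rows[None, :, :] - draws_rows
    return ImputationSet(values=values, draws=draws_rows, seed=int(seed),
                         columns=spec.columns)


def update_prior(imps: ImputationSet, weights: WeightMatrix) -> PriorSpec:
    """Weighted-moment M-step for the normal prior parameters.

    Each imputed value ``x~_i(b)`` carries mass ``q_i(b)/n``; the update is
    the weighted mean and covariance, eigenvalue-floored.
    """
    B, n, p = imps.values.shape
    q = weights.q.T[:, :, None] / n          # (B, n, 1)
    x = imps.values
    mean = np.sum(q * x, axis=(0, 1))
    dev = x - mean
    cov = np.einsum("bni,bnj->ij", q * dev, dev)
    prior = PriorSpec(mean=mean, cov=cov)
    if np.linalg.eigvalsh(prior.cov).min() <= 0:
        raise FloatingPointError("degenerate prior covariance after flooring")
    return prior


def m_step(y, imps: ImputationSet, weights: WeightMatrix, fitter,
           data: pd.DataFrame, stacked: pd.DataFrame | None = None,
           start=None):
    """Weighted refit on the stacked imputed data (nB rows)."""
    B, n, _ = imps.values.shape
    if stacked is None:
        stacked = stack_imputed_data(data, imps)
    y_rep = np.tile(np.asarray(y, dtype=float), B)
    q_flat = weights.q.T.reshape(B * n)
    try:
        return fitter.fit(y_rep, stacked, weights=q_flat, start=start)
    except Exception as exc:
        raise RuntimeError(f"M-step refit failed: {exc}") from exc


def effective_sample_size(weights: WeightMatrix) -> tuple[np.ndarray, float]:
    """Per-observation ESS_i = 1 / sum_b q_i(b)^2 and its mean.

    ESS is the number of equally-weighted Monte-Carlo draws the weighted
    imputation set is worth; it lies in [1, B] and diagnoses how well the
    prior proposal matches the posterior of the latent covariate.
    """
    ess = 1.0 / np.sum(weights.q**2, axis=1)
    return ess, float(ess.mean())


def observed_loglik(y, imps: ImputationSet, fitter, prior: PriorSpec, beta,
                    data: pd.DataFrame, stacked: pd.DataFrame | None = None,
                    check: bool = True, groups=None) -> float:
    """Monte-Carlo observed-data log-likelihood.

    ``l = sum_i log{ (1/B) sum_b f_Y(y_i|x~_i(b); beta) f_X(x~_i(b)) }``,
    the marginal over the fixed prior draws.  Equivalently the Q function
    minus the entropy of the importance weights (relative to uniform); both
    routes are computed and cross-checked.
    """
    B = imps.B
    logw = _grouped_logweights(y, imps, fitter, prior, beta, data, stacked,
                               groups)
    ll = float(np.sum(logsumexp(logw, axis=1) - np.log(B)))
    if check:
        q = _normalise_rows(logw).q
        with np.errstate(divide="ignore", invalid="ignore"):
            qlogq = np.where(q > 0, q * np.log(np.maximum(q, 1e-300)), 0.0)
        # Q (unpenalised part) minus the weight entropy, minus the n*log(B)
        # normalising constant of the uniform mixture
        q_fun = float(np.sum(q * logw))
        entropy = float(np.sum(qlogq))
        alt = q_fun - entropy - len(q) * np.log(B)
        if not np.isclose(ll, alt, atol=1e-8 * max(1.0, abs(ll))):
            raise AssertionError(
                f"observed log-likelihood routes disagree: {ll} vs {alt}"
            )
    return ll


def run_mcem(fitter, y, data: pd.DataFrame, spec: MeasurementErrorSpec,
             B: int = 50, epsilon: float = 1e-5, max_iter: int = 100,
             seed: int = 0, prior: PriorSpec | None = None,
             update_prior_each_iter: bool = True, compute_se: bool = True,
             ci_level: float = 0.95, verbose: bool = False,
             groups=None) -> MCEMResult:
    """Refit a naive model, correcting for known covariate measurement error.

    Parameters
    ----------
    fitter
        Any fitter satisfying the weighted-likelihood contract
        (:class:`~eivfit.fitters.GlmFitter`, :class:`~eivfit.fitters.GamFitter`,
        :class:`~eivfit.fitters.PosBinomialFitter`, ...).
    y, data
        Response vector and raw covariate data frame.  ``data`` holds both
        contaminated and error-free covariates; only the columns named in
        ``spec`` are imputed.
    spec
        Which columns are contaminated, and the known error covariance.
    B
        Number of fixed Monte-Carlo imputations (default 50).
    epsilon
        Convergence threshold on the max-norm relative coefficient change
        (default 1e-5).
    prior
        Structural prior for the latent covariates.  Default: moment
        corrected from the observed data, then re-estimated each iteration
        (set ``update_prior_each_iter=False`` to keep it fixed).
    groups
        Optional row-group labels.  Rows sharing a label form one
        observational unit: they share one error draw per imputation and one
        importance weight (used e.g. by the point-process quadrature, where
        a raster cell and the presences inside it carry the same measured
        covariate value).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    naive = fitter.fit(y, data)
    beta = naive.beta.copy()

    idx, G = _group_index(groups, n)
    if groups is None:
        imps = draw_imputations(data, spec, B, seed)
    else:
        imps = _draw_grouped_imputations(data, spec, B, seed, idx, G)
    _, rep = np.unique(idx, return_index=True)
    stacked = stack_imputed_data(data, imps)
    if prior is None:
        prior = initial_prior(data, spec, groups=groups)

    trace_rows = []
    converged = False
    n_iter = 0
    for t in range(1, max_iter + 1):
        logw = _grouped_logweights(y, imps, fitter, prior, beta, data,
                                   stacked, groups)
        q_group = _normalise_rows(logw).q
        weights = WeightMatrix(q=q_group[idx])
        ll = float(np.sum(logsumexp(logw, axis=1) - np.log(B)))
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite observed log-likelihood at iteration {t}; "
                f"trace so far: {trace_rows}"
            )
        fit = m_step(y, imps, weights, fitter, data, stacked, start=beta)
        if update_prior_each_iter:
            group_imps = ImputationSet(
                values=imps.values[:, rep, :], draws=imps.draws[:, rep, :],
                seed=imps.seed, columns=imps.columns)
            prior = update_prior(group_imps, WeightMatrix(q=q_group))
        delta = float(np.max(np.abs(fit.beta - beta)) /
                      (1.0 + np.max(np.abs(beta))))
        trace_rows.append({"iter": t, "loglik": ll, "max_delta": delta})
        if verbose:
            print(f"  iter {t:3d}  loglik {ll:.6f}  max|dbeta| {delta:.3e}")
        beta = fit.beta
        n_iter = t
        if delta < epsilon:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCEM did not converge in {max_iter} iterations "
            f"(last max-norm change {trace_rows[-1]['max_delta']:.3e})",
            RuntimeWarning,
        )

    # final E-step quantities at the converged coefficients
    logw = _grouped_logweights(y, imps, fitter, prior, beta, data, stacked,
                               groups)
    q_group = _normalise_rows(logw).q
    weights = WeightMatrix(q=q_group[idx])
    group_weights = WeightMatrix(q=q_group)
    ess, ess_mean = effective_sample_size(group_weights)
    ll_obs = observed_loglik(y, imps, fitter, prior, beta, data, stacked,
                             groups=groups)
    trace = pd.DataFrame(trace_rows)

    d = beta.size
    if compute_se:
        from .inference import (
            coefficient_covariance,
            louis_information,
            per_obs_score_jacobian,
        )

        scoreset = per_obs_score_jacobian(fitter, y, imps, beta, data,
                                          stacked, groups=groups)
        info = louis_information(scoreset, group_weights,
                                 penalty=fitter.penalty_matrix())
        cov, se, _ = coefficient_covariance(info, level=ci_level)
    else:
        cov = np.full((d, d), np.nan)
        se = np.full(d, np.nan)

    edf = fit.edf if fit.edf is not None else float(d)
    return MCEMResult(
        beta=beta, covariance=cov, se=se, ess=ess, ess_mean=ess_mean,
        loglik_obs=ll_obs, trace=trace, converged=converged, n_iter=n_iter,
        prior=prior, weights=weights, imputations=imps,
        param_names=getattr(fitter, "param_names", []), edf=edf,
        extra={"naive": naive, "dispersion": fitter.dispersion_,
               "group_weights": group_weights},
    )
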