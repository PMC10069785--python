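"""Domain containers for errors-in-variables MCEM fitting.

The classical measurement-error model observes ``W = X + U`` where ``X`` is
the true (latent) covariate and ``U ~ N(0, sigma_u)`` is independent noise
with *known* covariance.  These containers carry the pieces of the
iteratively reweighted MCEM correction: which covariates are contaminated
and by how much, the fixed Monte-Carlo imputations of the latent covariate,
the per-observation importance weights, and the final corrected fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementErrorSpec",
    "PriorSpec",
    "ImputationSet",
    "WeightMatrix",
    "FitResult",
    "MCEMResult",
]


def _as_cov_matrix(sigma_u, p: int) -> np.ndarray:
    """Promote a scalar / vector / matrix error variance to a p x p matrix."""
    s = np.asarray(sigma_u, dtype=float)
    if s.ndim == 0:
        if p != 1:
            # scalar with several contaminated covariates = common variance
            return np.eye(p) * float(s)
        return s.reshape(1, 1)
    if s.ndim == 1:
        if s.size != p:
            raise ValueError(
                f"sigma_u vector has length {s.size}, expected {p}"
            )
        return np.diag(s)
    if s.shape != (p, p):
        raise ValueError(f"sigma_u matrix has shape {s.shape}, expected {(p, p)}")
    return s


@dataclass(frozen=True)
class MeasurementErrorSpec:
    """Which covariates carry classical measurement error, and how much.

    Parameters
    ----------
    columns
        Names of the error-contaminated covariate columns (the latent ``X``
        whose noisy version ``W`` is observed).
    sigma_u
        Known error covariance.  A scalar (one contaminated covariate or a
        common variance), a vector of per-covariate variances, or a full
        p x p covariance matrix, in squared covariate units.
    """

    columns: tuple
    sigma_u: np.ndarray

    def __init__(self, columns, sigma_u):
        cols = tuple(columns) if not isinstance(columns, str) else (columns,)
        if len(set(cols)) != len(cols):
            raise ValueError("contaminated covariate names must be distinct")
        p = len(cols)
        mat = _as_cov_matrix(sigma_u, p)
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise ValueError(f"sigma_u is not symmetric:\n{mat}")
        eigvals = np.linalg.eigvalsh(mat)
        if eigvals.min() < -1e-10 * max(1.0, abs(eigvals.max())):
            raise ValueError(
                f"sigma_u is not positive semi-definite (eigenvalues {eigvals}):\n{mat}"
            )
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "sigma_u", mat)

    @property
    def p(self) -> int:
        return len(self.columns)

    @property
    def is_error_free(self) -> bool:
        return bool(np.all(self.sigma_u == 0.0))


@dataclass
class PriorSpec:
    """Multivariate-normal structural prior ``f_X`` for the latent covariates.

    ``cov`` eigenvalues are floored at ``floor_frac * trace(cov)`` so the
    density stays proper even when the moment-corrected initial estimate
    ``cov(W) - sigma_u`` is indefinite.
    """

    mean: np.ndarray
    cov: np.ndarray
    floor_frac: float = 1e-6

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        cov = 0.5 * (cov + cov.T)
        vals, vecs = np.linalg.eigh(cov)
        floor = self.floor_frac * max(np.trace(cov), self.floor_frac)
        vals = np.maximum(vals, floor)
        self.cov = (vecs * vals) @ vecs.T
        if self.mean.size != self.cov.shape[0]:
            raise ValueError("prior mean/cov dimension mismatch")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log density at each row of ``x`` (shape (..., p))."""
        x = np.asarray(x, dtype=float)
        p = self.mean.size
        chol = np.linalg.cholesky(self.cov)
        dev = x.reshape(-1, p) - self.mean
        z = np.linalg.solve(chol, dev.T)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out = -0.5 * (p * np.log(2 * np.pi) + logdet + np.sum(z * z, axis=0))
        return out.reshape(x.shape[:-1])


@dataclass(frozen=True)
class ImputationSet:
    """Fixed Monte-Carlo imputations of the latent covariates.

    ``values[b] = w_contaminated - draws[b]`` where ``draws[b]`` are i.i.d.
    N(0, sigma_u) proposals.  Drawn once per MCEM run and never redrawn:
    conditional on them the algorithm is an exact EM.
    """

    values: np.ndarray  # (B, n, p)
    draws: np.ndarray   # (B, n, p)
    seed: int
    columns: tuple

    @property
    def B(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def p(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class WeightMatrix:
    """Per-observation importance weights ``q[i, b]``, each row normalised."""

    q: np.ndarray  # (n, B)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if not np.all(np.isfinite(q)):
            raise ValueError("importance weights contain non-finite entries")
        if np.any(q < 0):
            raise ValueError("importance weights must be non-negative")
        rows = q.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("importance weight rows must sum to 1")
        object.__setattr__(self, "q", q)

    @property
    def n(self) -> int:
        return self.q.shape[0]

    @property
    def B(self) -> int:
        return self.q.shape[1]


@dataclass
class FitResult:
    """Result of one weighted maximum / penalised likelihood fit."""

    beta: np.ndarray
    linear_predictor: np.ndarray
    loglik: float
    converged: bool = True
    edf: float | None = None
    dispersion: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class MCEMResult:
    """Corrected fit from the iteratively reweighted MCEM algorithm."""

    beta: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    ess: np.ndarray            # per-observation effective sample size
    ess_mean: float
    loglik_obs: float
    trace: pd.DataFrame        # per-iteration (iter, loglik, max_delta)
    converged: bool
    n_iter: int
    prior: PriorSpec
    weights: WeightMatrix
    imputations: ImputationSet
    param_names: list = field(default_factory=list)
    edf: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        k = self.edf if self.edf is not None else self.beta.size
        return -2.0 * self.loglik_obs + 2.0 * k

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.beta - z * self.se
        hi = self.beta + z * self.se
        names = self.param_names or [f"b{j}" for j in range(self.beta.size)]
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "lower": lo, "upper": hi},
            index=names,
        )

    def summary_dict(self) -> dict:
        names = self.param_names or [f"b{j}" for j in range(self.beta.size)]
        return {
            "coefficients": dict(zip(names, map(float, self.beta))),
            "se": dict(zip(names, map(float, self.se))),
            "covariance": self.covariance.tolist(),
            "ess_mean": float(self.ess_mean),
            "ess_per_obs_summary": {
                "min": float(np.min(self.ess)),
                "q25": float(np.percentile(self.ess, 25)),
                "median": float(np.median(self.ess)),
                "q75": float(np.percentile(self.ess, 75)),
                "max": float(np.max(self.ess)),
            },
            "loglik": float(self.loglik_obs),
            "aic": float(self.aic),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }
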