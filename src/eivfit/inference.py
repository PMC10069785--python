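"""Louis observed information and corrected standard errors.

The converged MCEM fit maximises a weighted complete-data likelihood, so
its Fisher information overstates the precision of the coefficients: it
ignores the uncertainty in the latent covariates.  The Louis decomposition
recovers the observed-data information as

    I_W = I_X - I_{X|W}
        = -sum_i E[J_i] - sum_i E[s_i s_i'] + sum_i E[s_i] E[s_i]',

with the conditional expectations over the latent covariate replaced by
importance-weighted averages across the B imputations.  Standard errors are
then the square roots of the diagonal of I_W^{-1}, solved via a QR
factorisation rather than an explicit inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .types import ImputationSet, WeightMatrix

__all__ = [
    "ScoreSet",
    "per_obs_score_jacobian",
    "louis_information",
    "coefficient_covariance",
    "naive_covariance",
]


@dataclass(frozen=True)
class ScoreSet:
    """Per-observation, per-imputation gradients and Jacobians.

    ``scores`` has shape (n, B, d), ``jacobians`` shape (n, B, d, d), for a
    coefficient vector of length d.
    """

    scores: np.ndarray
    jacobians: np.ndarray

    def __post_init__(self):
        s, J = self.scores, self.jacobians
        if s.ndim != 3 or J.ndim != 4 or J.shape[:3] != (*s.shape[:2], s.shape[2]):
            raise ValueError("inconsistent score/jacobian dimensions")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(J))):
            raise ValueError("non-finite entries in scores or jacobians")


def per_obs_score_jacobian(fitter, y, imps: ImputationSet, beta,
                           data, stacked=None, groups=None) -> ScoreSet:
    """Evaluate analytic per-observation scores and Jacobians at ``beta``.

    Uses the fitter's exponential-family expressions at every imputation.
    With ``groups``, rows of a group form one observational unit and their
    scores/Jacobians are summed.
    """
    from .mcem import _group_index, _reduce_rows, stack_imputed_data

    B, n, _ = imps.values.shape
    if stacked is None:
        stacked = stack_imputed_data(data, imps)
    y_rep = np.tile(np.asarray(y, dtype=float), B)
    s = fitter.score_i(y_rep, stacked, beta)          # (nB, d)
    J = fitter.jacobian_i(y_rep, stacked, beta)       # (nB, d, d)
    d = s.shape[1]
    scores = s.reshape(B, n, d).transpose(1, 0, 2)
    jacobians = J.reshape(B, n, d, d).transpose(1, 0, 2, 3)
    if groups is not None:
        idx, G = _group_index(groups, n)
        scores = _reduce_rows(scores, idx, G)
        jacobians = _reduce_rows(jacobians, idx, G)
    return ScoreSet(scores=scores, jacobians=jacobians)


def louis_information(scoreset: ScoreSet, weights: WeightMatrix,
                      penalty: np.ndarray | None = None) -> np.ndarray:
    """Monte-Carlo Louis observed information.

    ``I_W = -sum_ib q_ib J_ib - sum_ib q_ib s_ib s_ib' + sum_i sbar_i sbar_i'``
    with ``sbar_i = sum_b q_ib s_ib``.  For penalised fits the penalty
    Hessian is added to the Jacobian term.  Raises if the result is not
    positive definite (Monte-Carlo error too large -- increase B).
    """
    q = weights.q                       # (n, B)
    s = scoreset.scores                 # (n, B, d)
    J = scoreset.jacobians              # (n, B, d, d)
    info = -np.einsum("nb,nbij->ij", q, J)
    if penalty is not None:
        info = info + penalty
    info -= np.einsum("nb,nbi,nbj->ij", q, s, s)
    sbar = np.einsum("nb,nbi->ni", q, s)
    info += np.einsum("ni,nj->ij", sbar, sbar)
    info = 0.5 * (info + info.T)
    eigmin = float(np.linalg.eigvalsh(info).min())
    if eigmin <= 0:
        raise np.linalg.LinAlgError(
            f"Louis information is not positive definite (min eigenvalue "
            f"{eigmin:.3e}): Monte-Carlo error is too large, increase B"
        )
    return info


def naive_covariance(fitter, y, data, beta) -> tuple[np.ndarray, np.ndarray]:
    """Model-based (covariance, se) of an uncorrected complete-data fit.

    The observed information ``-sum_i J_i`` (plus the penalty Hessian for
    penalised fitters) at the naive estimate; the measurement-error-free
    limit of the Louis information.
    """
    J = fitter.jacobian_i(np.asarray(y, dtype=float), data, beta)
    info = -J.sum(axis=0)
    pen = fitter.penalty_matrix()
    if pen is not None:
        info = info + pen
    cov, se, _ = coefficient_covariance(info)
    return cov, se


def coefficient_covariance(info: np.ndarray, level: float = 0.95
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance, SEs and Wald intervals' half-widths from I_W.

    Solved through a QR factorisation of the information matrix.  Returns
    ``(covariance, se, z_halfwidth)`` where the Wald interval for
    coefficient j is ``beta_j +/- z_halfwidth[j]``.
    """
    info = np.asarray(info, dtype=float)
    cond = np.linalg.cond(info)
    if cond > 1e12:
        warnings.warn(
            f"Louis information is ill-conditioned (cond={cond:.2e}); "
            "standard errors may be unstable", RuntimeWarning,
        )
    Q, R = linalg.qr(info)
    cov = linalg.solve_triangular(R, Q.T)
    cov = 0.5 * (cov + cov.T)
    var = np.diag(cov).copy()
    if np.any(var <= 0):
        raise np.linalg.LinAlgError(
            "non-positive variance from the Louis information; increase B"
        )
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return cov, se, z * se
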