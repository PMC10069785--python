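"""Poisson point-process models via Berman--Turner quadrature.

A presence-only point pattern with log-linear intensity
``log lambda(s) = x(s)' beta`` has log-likelihood

    l(beta) = sum_i log lambda(s_i) - int_A lambda(s) ds.

The Berman--Turner device approximates the integral on a regular grid and
rewrites the whole objective as a *weighted Poisson* log-likelihood

    l(beta) ~= sum_j w_j { y_j log lambda(s_j) - lambda(s_j) }

with pseudo-responses ``y_j = 1/w_j`` at presence points (weight
``epsilon = 1e-6``) and ``y_j = 0`` at quadrature points (weight ``|A|/n``).
Any weighted Poisson GLM fitter then estimates ``beta``; nesting that fitter
in the MCEM wrapper corrects for measurement error in spatial covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitters import GlmFitter
from .mcem import run_mcem
from .types import FitResult, MCEMResult, MeasurementErrorSpec

__all__ = [
    "PointPattern",
    "QuadratureScheme",
    "build_berman_turner",
    "fit_ppm",
    "predict_intensity",
    "PRESENCE_EPSILON",
]

PRESENCE_EPSILON = 1e-6
QUAD_WEIGHT_COL = "_quad_w"


@dataclass(frozen=True)
class PointPattern:
    """Presence locations inside a rectangular observation window."""

    coords: np.ndarray               # (m, 2)
    window: tuple                    # (x0, x1, y0, y1)

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.shape[0] < 1 or coords.shape[1] != 2:
            raise ValueError("point pattern needs at least one (x, y) location")
        x0, x1, y0, y1 = self.window
        inside = ((coords[:, 0] >= x0) & (coords[:, 0] <= x1) &
                  (coords[:, 1] >= y0) & (coords[:, 1] <= y1))
        if not np.all(inside):
            raise ValueError(
                f"points outside the window: {coords[~inside].tolist()}"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    @property
    def area(self) -> float:
        x0, x1, y0, y1 = self.window
        return float((x1 - x0) * (y1 - y0))


@dataclass
class QuadratureScheme:
    """Berman--Turner pseudo-data: locations, weights, responses, covariates."""

    points: np.ndarray               # (m + n_quad, 2); presences first
    weights: np.ndarray
    pseudo_response: np.ndarray
    data: pd.DataFrame               # covariates + quadrature-weight column
    m: int
    n_quad: int
    area: float
    groups: np.ndarray | None = None  # raster-cell id per row (latent units)

    @property
    def is_presence(self) -> np.ndarray:
        mask = np.zeros(len(self.weights), dtype=bool)
        mask[: self.m] = True
        return mask


def _nearest_cell(raster: pd.DataFrame, coords: np.ndarray,
                  cov_cols: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Nearest grid-cell covariate lookup (values and cell indices)."""
    gx = raster["x"].to_numpy(dtype=float)
    gy = raster["y"].to_numpy(dtype=float)
    out = {}
    idx = np.empty(len(coords), dtype=int)
    for i, (px, py) in enumerate(coords):
        idx[i] = int(np.argmin((gx - px) ** 2 + (gy - py) ** 2))
    for c in cov_cols:
        out[c] = raster[c].to_numpy()[idx]
    return pd.DataFrame(out), idx


def build_berman_turner(pattern: PointPattern,
                        covariate_raster: pd.DataFrame | None = None,
                        grid_resolution: float | None = None,
                        epsilon: float = PRESENCE_EPSILON) -> QuadratureScheme:
    """Assemble the Berman--Turner quadrature scheme.

    Quadrature points are the cells of ``covariate_raster`` (columns ``x``,
    ``y`` plus covariate columns on a regular grid covering the window), or
    a regular grid of spacing ``grid_resolution`` when no raster is given
    (intercept-only models).  Each quadrature point gets weight ``|A|/n``;
    presences are appended with weight ``epsilon`` and pseudo-response
    ``1/epsilon``, and pick up covariates from the nearest raster cell.
    """
    x0, x1, y0, y1 = pattern.window
    if covariate_raster is not None:
        quad = covariate_raster[["x", "y"]].to_numpy(dtype=float)
        cov_cols = [c for c in covariate_raster.columns if c not in ("x", "y")]
        # raster must cover every presence, up to half a cell beyond its rim
        ux = np.unique(quad[:, 0])
        uy = np.unique(quad[:, 1])
        half_x = 0.5 * (np.min(np.diff(ux)) if ux.size > 1 else np.inf)
        half_y = 0.5 * (np.min(np.diff(uy)) if uy.size > 1 else np.inf)
        outside = ((pattern.coords[:, 0] < ux.min() - half_x) |
                   (pattern.coords[:, 0] > ux.max() + half_x) |
                   (pattern.coords[:, 1] < uy.min() - half_y) |
                   (pattern.coords[:, 1] > uy.max() + half_y))
        if np.any(outside):
            raise ValueError(
                "presences outside raster coverage: "
                f"{pattern.coords[outside].tolist()}"
            )
    else:
        if grid_resolution is None:
            raise ValueError("need a covariate raster or a grid resolution")
        xs = np.arange(x0 + grid_resolution / 2, x1, grid_resolution)
        ys = np.arange(y0 + grid_resolution / 2, y1, grid_resolution)
        quad = np.array([(a, b) for b in ys for a in xs])
        cov_cols = []
    n_quad = quad.shape[0]
    area = pattern.area
    points = np.vstack([pattern.coords, quad])
    weights = np.concatenate([
        np.full(pattern.m, epsilon), np.full(n_quad, area / n_quad)
    ])
    y = np.concatenate([np.full(pattern.m, 1.0 / epsilon), np.zeros(n_quad)])
    if cov_cols:
        pres_cov, cell_idx = _nearest_cell(covariate_raster, pattern.coords,
                                           cov_cols)
        quad_cov = covariate_raster[cov_cols].reset_index(drop=True)
        data = pd.concat([pres_cov, quad_cov], ignore_index=True)
        # a presence shares its raster cell's (single) measured covariate,
        # so presence and cell form one latent observational unit
        groups = np.concatenate([cell_idx, np.arange(n_quad)])
    else:
        data = pd.DataFrame(index=range(len(points)))
        groups = np.arange(len(points))
    data[QUAD_WEIGHT_COL] = weights
    return QuadratureScheme(points=points, weights=weights, pseudo_response=y,
                            data=data, m=pattern.m, n_quad=n_quad, area=area,
                            groups=groups)


def ppm_fitter(terms, intercept: bool = True) -> GlmFitter:
    """Weighted Poisson GLM fitter carrying the quadrature weights."""
    return GlmFitter("poisson", terms, base_weight_col=QUAD_WEIGHT_COL,
                     intercept=intercept)


def ppm_loglik(scheme: QuadratureScheme, fitter: GlmFitter, beta) -> float:
    """Direct point-process log-likelihood sum_i log lambda(s_i) - sum_j w_j lambda(s_j)."""
    eta = fitter.predict(scheme.data, beta)
    lam = np.exp(eta)
    pres = scheme.is_presence
    return float(np.sum(eta[pres]) - np.sum(scheme.weights * lam))


def fit_ppm(scheme: QuadratureScheme, terms,
            me_spec: MeasurementErrorSpec | None = None, B: int = 50,
            seed: int = 0, **mcem_kw) -> tuple[GlmFitter, FitResult | MCEMResult]:
    """Fit the point-process model, optionally correcting measurement error.

    Without ``me_spec`` this is the naive weighted-Poisson fit.  With it,
    the covariate value attached to every presence and quadrature point is
    treated as independently contaminated and the fit runs through the MCEM
    wrapper; the Berman--Turner weights and the importance weights compose
    multiplicatively in each M-step.
    """
    fitter = ppm_fitter(terms)
    fitter.builder.freeze(scheme.data)
    if me_spec is None or me_spec.is_error_free:
        return fitter, fitter.fit(scheme.pseudo_response, scheme.data)
    result = run_mcem(fitter, scheme.pseudo_response, scheme.data, me_spec,
                      B=B, seed=seed, groups=scheme.groups, **mcem_kw)
    return fitter, result


def predict_intensity(fitter: GlmFitter, beta, raster: pd.DataFrame,
                      shift: dict[str, float] | None = None) -> pd.DataFrame:
    """Predicted intensity surface, optionally under a covariate scenario.

    ``shift`` maps covariate names to additive offsets applied *before*
    evaluating the fitted model (e.g. ``{"min_temp": 1.0}`` for a +1 degree
    warming scenario).
    """
    model_cols = set(fitter.builder.covariate_names())
    data = raster.copy()
    for col, delta in (shift or {}).items():
        if col not in model_cols:
            raise ValueError(
                f"shift column {col!r} is not a model covariate "
                f"(model uses {sorted(model_cols)})"
            )
        data[col] = data[col] + delta
    eta = fitter.predict(data, np.asarray(beta, dtype=float))
    out = raster[["x", "y"]].copy() if {"x", "y"} <= set(raster.columns) \
        else pd.DataFrame(index=raster.index)
    out["intensity"] = np.exp(eta)
    return out
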