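"""Model terms and design-matrix construction.

Terms are written in a small mini-language::

    "x"            raw covariate
    "poly(x, 2)"   raw polynomial (x, x^2, ...) of a covariate
    "s(x, k=10)"   penalised B-spline smooth of a covariate
    "offset(col)"  offset column (added to the linear predictor, no coefficient)

Design matrices are a pure function of (terms, data): polynomial and spline
columns of an error-contaminated covariate are always rebuilt from the raw
imputed values, never imputed at the transformed scale.  Spline knots (and
the centering constraint for identifiability next to an intercept) are
computed once, from the observed data, and frozen so that coefficients are
comparable across EM iterations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "Term",
    "RawTerm",
    "PolyTerm",
    "SplineTerm",
    "OffsetTerm",
    "parse_term",
    "bspline_basis",
    "difference_penalty",
    "DesignBuilder",
]


@dataclass(frozen=True)
class Term:
    name: str


@dataclass(frozen=True)
class RawTerm(Term):
    pass


@dataclass(frozen=True)
class PolyTerm(Term):
    degree: int = 2


@dataclass(frozen=True)
class SplineTerm(Term):
    k: int = 10          # number of basis functions before the constraint
    degree: int = 3
    penalty_order: int = 2
    expand: float = 0.3  # fractional range padding of the basis support


@dataclass(frozen=True)
class OffsetTerm(Term):
    pass


_POLY_RE = re.compile(r"^poly\(\s*(\w+)\s*,\s*(\d+)\s*\)$")
_SPLINE_RE = re.compile(
    r"^s\(\s*(\w+)\s*(?:,\s*k\s*=\s*(\d+)\s*)?"
    r"(?:,\s*expand\s*=\s*([0-9.]+)\s*)?\)$"
)
_OFFSET_RE = re.compile(r"^offset\(\s*(\w+)\s*\)$")


def parse_term(expr: str) -> Term:
    """Parse one term expression of the mini-language."""
    expr = expr.strip()
    m = _POLY_RE.match(expr)
    if m:
        return PolyTerm(m.group(1), degree=int(m.group(2)))
    m = _SPLINE_RE.match(expr)
    if m:
        k = int(m.group(2)) if m.group(2) else 10
        expand = float(m.group(3)) if m.group(3) else 0.3
        return SplineTerm(m.group(1), k=k, expand=expand)
    m = _OFFSET_RE.match(expr)
    if m:
        return OffsetTerm(m.group(1))
    if re.match(r"^\w+$", expr):
        return RawTerm(expr)
    raise ValueError(f"cannot parse model term {expr!r}")


def bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Evaluate the full B-spline basis on ``x`` for a padded knot vector.

    The basis satisfies partition of unity (rows sum to 1) between the
    boundary knots.
    """
    x = np.asarray(x, dtype=float)
    dm = BSpline.design_matrix(x, knots, degree, extrapolate=True)
    return dm.toarray()


def make_knots(x: np.ndarray, k: int, degree: int = 3, expand: float = 0.3) -> np.ndarray:
    """Equally spaced P-spline knots covering an expanded data range.

    The working interval stretches ``expand`` times the data range beyond the
    observed extremes, so Monte-Carlo imputations of a noisy covariate stay
    inside the support of the basis.  Knots are uniform and unclamped
    (``degree`` extra knots beyond each end), the standard P-spline
    construction: with uniform knots the Greville abscissae are linear in the
    coefficient index, so the null space of the order-2 difference penalty is
    exactly the linear-in-x trend.
    """
    x = np.asarray(x, dtype=float)
    n_spans = k - degree
    if n_spans < 1:
        raise ValueError(f"k={k} too small for degree {degree}")
    lo, hi = float(np.min(x)), float(np.max(x))
    pad = expand * max(hi - lo, 1e-8)
    a, b = lo - pad, hi + pad
    h = (b - a) / n_spans
    return a + h * np.arange(-degree, k + 1)


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """P-spline penalty matrix D'D for order-``order`` coefficient differences."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


@dataclass
class _SplineInfo:
    term: SplineTerm
    knots: np.ndarray
    constraint: np.ndarray   # k x (k-1) centering reparameterisation
    penalty: np.ndarray      # (k-1) x (k-1), constraint-transformed D'D
    sl: slice                # columns in the design matrix
    lam: float = 1.0


class DesignBuilder:
    """Build design matrices (and spline penalties) from terms and data.

    Parameters
    ----------
    terms
        Term objects or mini-language strings.
    intercept
        Prepend a column of ones (default True).
    """

    def __init__(self, terms, intercept: bool = True):
        self.terms = [parse_term(t) if isinstance(t, str) else t for t in terms]
        self.intercept = intercept
        self._frozen = False
        self.spline_info: dict[str, _SplineInfo] = {}
        self.column_names: list[str] = []

    # -- freezing -----------------------------------------------------------
    def freeze(self, data: pd.DataFrame) -> "DesignBuilder":
        """Compute knots and identifiability constraints from observed data."""
        names = ["const"] if self.intercept else []
        col = len(names)
        for t in self.terms:
            if isinstance(t, OffsetTerm):
                continue
            if isinstance(t, RawTerm):
                names.append(t.name)
                col += 1
            elif isinstance(t, PolyTerm):
                for d in range(1, t.degree + 1):
                    names.append(t.name if d == 1 else f"{t.name}^{d}")
                col += t.degree
            elif isinstance(t, SplineTerm):
                x = data[t.name].to_numpy(dtype=float)
                knots = make_knots(x, t.k, t.degree, expand=t.expand)
                B = bspline_basis(x, knots, t.degree)
                # centering constraint: smooth sums to zero over the observed
                # data, keeping the basis identifiable next to the intercept
                c = B.mean(axis=0)
                Z = _null_space_of_row(c)
                S = Z.T @ difference_penalty(t.k, t.penalty_order) @ Z
                ncol = Z.shape[1]
                sl = slice(col, col + ncol)
                self.spline_info[t.name] = _SplineInfo(t, knots, Z, S, sl)
                names += [f"s({t.name}).{j}" for j in range(ncol)]
                col += ncol
            else:
                raise TypeError(f"unknown term {t}")
        self.column_names = names
        self._frozen = True
        return self

    # -- building -----------------------------------------------------------
    def build(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, offset) for the given data."""
        if not self._frozen:
            self.freeze(data)
        n = len(data)
        cols = []
        if self.intercept:
            cols.append(np.ones(n))
        offset = np.zeros(n)
        for t in self.terms:
            if isinstance(t, OffsetTerm):
                offset = offset + data[t.name].to_numpy(dtype=float)
                continue
            x = data[t.name].to_numpy(dtype=float)
            if isinstance(t, RawTerm):
                cols.append(x)
            elif isinstance(t, PolyTerm):
                for d in range(1, t.degree + 1):
                    cols.append(x**d)
            elif isinstance(t, SplineTerm):
                info = self.spline_info[t.name]
                B = bspline_basis(x, info.knots, t.degree)
                cols.append(B @ info.constraint)
        X = np.column_stack(cols) if cols else np.empty((n, 0))
        return X, offset

    # -- penalties ----------------------------------------------------------
    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    @property
    def has_splines(self) -> bool:
        return bool(self.spline_info)

    def penalty_matrix(self, lambdas: dict[str, float] | None = None) -> np.ndarray:
        """Full-dimension block penalty sum_j lambda_j S_j."""
        S = np.zeros((self.n_columns, self.n_columns))
        for name, info in self.spline_info.items():
            lam = info.lam if lambdas is None else lambdas.get(name, info.lam)
            S[info.sl, info.sl] += lam * info.penalty
        return S

    def covariate_names(self) -> list[str]:
        """Raw covariate columns the design depends on (offsets included)."""
        return [t.name for t in self.terms]


def _null_space_of_row(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of the row vector ``c``."""
    c = np.asarray(c, dtype=float).reshape(1, -1)
    if np.allclose(c, 0):
        return np.eye(c.size)
    _, _, Vt = np.linalg.svd(c, full_matrices=True)
    return Vt[1:].T
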