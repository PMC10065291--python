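"""Spline bases for distributed-lag models and temporal trend fitting.

The lag dimension of a distributed-lag model is expanded in a small spline
basis so that a handful of coefficients describe a smooth lag-response curve.
Two families are provided: natural cubic splines (linear beyond the boundary
knots, zero second derivative at the boundaries) and quadratic B-splines.
The same natural-cubic construction doubles as the long-term-trend basis in
the weather imputation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "natural_cubic_basis",
    "quadratic_bspline_basis",
    "log_lag_knots",
    "LagBasis",
    "lag_basis",
]


def natural_cubic_basis(
    x: np.ndarray,
    knots: np.ndarray,
    include_intercept: bool = True,
) -> np.ndarray:
    """Natural cubic spline basis evaluated at ``x``.

    Uses the truncated-power construction: with knots xi_1 < ... < xi_K the
    basis is {1, x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}} where
    ``d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)``.
    The span is exactly the cubic splines that are linear outside
    [xi_1, xi_K] with zero second derivative at the boundary knots.

    Parameters
    ----------
    x : array
        Evaluation points (any shape; flattened to rows).
    knots : array
        All knots, boundary included, strictly increasing, length K >= 2.
    include_intercept : bool
        If True the constant column is kept and the basis has K columns;
        if False it is dropped (K - 1 columns), the convention used when an
        intercept is absorbed elsewhere (e.g. by stratum conditioning).

    Returns
    -------
    ndarray of shape (len(x), K) or (len(x), K - 1).
    """
    x = np.asarray(x, dtype=float).ravel()
    knots = np.asarray(knots, dtype=float).ravel()
    if knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing with length >= 2")
    K = knots.size

    def trunc3(t: np.ndarray) -> np.ndarray:
        return np.clip(t, 0.0, None) ** 3

    cols = [np.ones_like(x), x]
    if K > 2:
        dK1 = (trunc3(x - knots[K - 2]) - trunc3(x - knots[K - 1])) / (
            knots[K - 1] - knots[K - 2]
        )
        for k in range(K - 2):
            dk = (trunc3(x - knots[k]) - trunc3(x - knots[K - 1])) / (
                knots[K - 1] - knots[k]
            )
            cols.append(dk - dK1)
    B = np.column_stack(cols)
    if not include_intercept:
        B = B[:, 1:]
    return B


def quadratic_bspline_basis(x: np.ndarray, df: int, boundary: tuple[float, float],
                            interior_knots: np.ndarray | None = None) -> np.ndarray:
    """Quadratic B-spline basis with ``df`` columns (intercept implicit in span).

    ``df`` columns require ``df - 3`` interior knots (degree 2 plus one).
    Interior knots default to equally spaced points inside the boundary.
    """
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = float(boundary[0]), float(boundary[1])
    n_inner = df - 3
    if n_inner < 0:
        raise ValueError("quadratic b-spline needs df >= 3")
    if interior_knots is None:
        interior_knots = np.linspace(lo, hi, n_inner + 2)[1:-1]
    interior_knots = np.asarray(interior_knots, dtype=float)
    if interior_knots.size != n_inner:
        raise ValueError(f"df={df} requires {n_inner} interior knots")
    t = np.concatenate([[lo] * 3, interior_knots, [hi] * 3])
    xc = np.clip(x, lo, hi)  # B-splines are zero outside; lag grid never exceeds
    return BSpline.design_matrix(xc, t, 2).toarray()


def log_lag_knots(L: int, n_knots: int = 2) -> np.ndarray:
    """Interior lag knots equally spaced on the log scale of [1, L].

    For ``n_knots`` knots the positions are ``exp(i * log(L) / (n_knots + 1))``
    for i = 1..n_knots: equally spaced interior points of [log 1, log L],
    mapped back to the lag scale. Lag 0 cannot be logged, so the boundary
    knots sit at lag 0 and lag L on the natural scale.
    """
    if L < 2:
        raise ValueError("lag length must be >= 2 for log-spaced knots")
    if n_knots < 1:
        raise ValueError("need at least one interior knot")
    logL = np.log(L)
    return np.exp(np.arange(1, n_knots + 1) * logL / (n_knots + 1))


@dataclass
class LagBasis:
    """Lag grid 0..L with its basis matrix (rows = lags, columns = df)."""

    lags: np.ndarray
    matrix: np.ndarray
    family: str
    knots: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.lags.size:
            raise ValueError("basis rows must match the lag grid")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("lag basis matrix is rank deficient")

    @property
    def L(self) -> int:
        return int(self.lags.max())

    @property
    def df(self) -> int:
        return self.matrix.shape[1]


def lag_basis(L: int, family: str = "ns", df: int = 4) -> LagBasis:
    """Build the lag basis over the integer lag grid 0..L.

    family "ns": natural cubic spline, boundary knots at 0 and L, ``df - 2``
    interior knots equally spaced on the log lag scale, intercept included
    (so df = interior knots + 2). family "bs2": quadratic B-spline with
    ``df - 3`` log-spaced interior knots. family "identity": one indicator
    column per lag (the unconstrained distributed-lag model).
    """
    lags = np.arange(L + 1)
    if family == "identity":
        return LagBasis(lags, np.eye(L + 1), "identity", lags.astype(float))
    if family == "ns":
        inner = log_lag_knots(L, df - 2)
        knots = np.concatenate([[0.0], inner, [float(L)]])
        B = natural_cubic_basis(lags, knots, include_intercept=True)
        return LagBasis(lags, B, "ns", knots)
    if family == "bs2":
        inner = log_lag_knots(L, df - 3) if df > 3 else None
        B = quadratic_bspline_basis(lags, df, (0.0, float(L)), inner)
        knots = inner if inner is not None else np.array([])
        return LagBasis(lags, B, "bs2", knots)
    raise ValueError(f"unknown lag basis family: {family!r}")
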