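"""Cross-bases and effect summaries for distributed-lag non-linear models.

A cross-basis encodes an exposure's effect jointly over the exposure value
and the lag. Here the heat-wave indicator enters linearly in exposure and is
basis-expanded in lag (design row t = sum_l HW[t-l] * B[l, :]); absolute
humidity enters through the full tensor of a natural-cubic predictor basis
(df 4, no intercept — absorbed by stratum conditioning) with a lag basis
(df 4), giving 16 columns. Effect summaries exponentiate linear contrasts of
the fitted coefficients: the cumulative odds ratio uses the column sums of
the lag basis over lags 0..L; lag-specific odds ratios use single rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import LagBasis, lag_basis, natural_cubic_basis

__all__ = [
    "CrossBasis",
    "crossbasis_hw",
    "crossbasis_ah",
    "CumulativeEffect",
    "cumulative_effect",
    "lag_specific_effects",
]


@dataclass
class CrossBasis:
    """Design columns plus the metadata needed for contrasts."""

    columns: np.ndarray
    lag_basis: LagBasis
    names: list[str]
    predictor_knots: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def df(self) -> int:
        return self.columns.shape[1]


def crossbasis_hw(lagged_hw: np.ndarray, lb: LagBasis) -> CrossBasis:
    """Heat-wave cross-basis: linear in exposure, spline-expanded in lag.

    ``lagged_hw[i, l]`` is the heat-wave indicator l days before row i's
    date. The design row is the lag-weighted sum of basis rows, so an
    all-zero lag vector maps to the zero row and, with an identity lag
    basis, the design equals the raw lagged vector.
    """
    lagged_hw = np.asarray(lagged_hw, dtype=float)
    if lagged_hw.shape[1] != lb.matrix.shape[0]:
        raise ValueError("lag vector length must equal the lag-basis rows")
    cols = lagged_hw @ lb.matrix
    names = [f"hw_b{j}" for j in range(lb.df)]
    return CrossBasis(cols, lb, names)


def crossbasis_ah(
    lagged_ah: np.ndarray,
    lb: LagBasis | None = None,
    predictor_df: int = 4,
    predictor_knots: np.ndarray | None = None,
    prefix: str = "ah",
) -> CrossBasis:
    """Absolute-humidity cross-basis: spline x spline tensor.

    Predictor dimension: natural cubic spline with ``predictor_df`` columns,
    no intercept (boundary knots at the observed range, interior knots at
    equally spaced quantiles). Lag dimension: the supplied lag basis
    (default natural cubic, df 4, log-spaced knots). Total columns =
    predictor_df x lag df.
    """
    lagged_ah = np.asarray(lagged_ah, dtype=float)
    L = lagged_ah.shape[1] - 1
    if lb is None:
        lb = lag_basis(L, "ns", 4)
    if lb.matrix.shape[0] != L + 1:
        raise ValueError("lag basis rows must match the lag vector length")
    if predictor_knots is None:
        flat = lagged_ah.ravel()
        # df columns without intercept need df + 1 knots
        probs = np.linspace(0, 1, predictor_df + 1)
        predictor_knots = np.quantile(flat, probs)
        predictor_knots = np.unique(predictor_knots)
        if predictor_knots.size < 2:  # constant predictor: spread artificially
            predictor_knots = np.array(
                [predictor_knots[0] - 1.0, predictor_knots[0] + 1.0]
            )
    P = natural_cubic_basis(
        lagged_ah.ravel(), predictor_knots, include_intercept=False
    ).reshape(lagged_ah.shape[0], L + 1, -1)
    cols = np.einsum("nlp,lq->npq", P, lb.matrix)
    cols = cols.reshape(lagged_ah.shape[0], -1)
    names = [
        f"{prefix}_p{i}_l{j}" for i in range(P.shape[2]) for j in range(lb.df)
    ]
    return CrossBasis(cols, lb, names, np.asarray(predictor_knots))


@dataclass
class CumulativeEffect:
    """Cumulative odds ratio over lags 0..L with its Wald interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")
        if min(self.odds_ratio, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratios must be positive")


def _z(level: float) -> float:
    return 1.96 if abs(level - 0.95) < 1e-12 else float(
        stats.norm.ppf(0.5 + level / 2)
    )


def cumulative_effect(
    beta_hw: np.ndarray,
    cov_hw: np.ndarray,
    lb: LagBasis,
    level: float = 0.95,
    label: str = "",
) -> CumulativeEffect:
    """Cumulative odds ratio: contrast = column sums of the lag basis.

    With an identity lag basis this reduces to exp(sum_l beta_l). ``beta_hw``
    and ``cov_hw`` are the heat-wave slice of the fitted coefficients and
    covariance.
    """
    c = lb.matrix.sum(axis=0)
    log_or = float(c @ beta_hw)
    se = float(np.sqrt(c @ cov_hw @ c))
    z = _z(level)
    return CumulativeEffect(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or=log_or,
        se=se,
        label=label,
    )


def lag_specific_effects(
    beta_hw: np.ndarray,
    cov_hw: np.ndarray,
    lb: LagBasis,
    level: float = 0.95,
) -> "np.ndarray":
    """Per-lag odds ratios with Wald intervals.

    Returns a structured record array with fields lag, or, ci_low, ci_high,
    log_or, se. With an identity basis OR_l = exp(beta_l), and the sum of
    the per-lag log odds ratios equals the cumulative log odds ratio.
    """
    z = _z(level)
    B = lb.matrix
    log_or = B @ beta_hw
    se = np.sqrt(np.einsum("ij,jk,ik->i", B, cov_hw, B))
    rec = np.zeros(
        B.shape[0],
        dtype=[("lag", int), ("or", float), ("ci_low", float),
               ("ci_high", float), ("log_or", float), ("se", float)],
    )
    rec["lag"] = lb.lags
    rec["log_or"] = log_or
    rec["se"] = se
    rec["or"] = np.exp(log_or)
    rec["ci_low"] = np.exp(log_or - z * se)
    rec["ci_high"] = np.exp(log_or + z * se)
    return rec
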