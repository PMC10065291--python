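"""Station quality control, hourly aggregation and EM imputation.

A city-scale monitoring network reports daily (or hourly) mean temperature
and relative humidity with gaps. Stations with too much missingness are
dropped; the remaining multivariate daily series is completed with an
expectation-maximization (EM) algorithm that models the cross-station vector
of daily values as multivariate normal around station-specific smooth
seasonal/trend curves (natural cubic splines in time, a fixed number of
degrees of freedom per year) with a free cross-station covariance. Missing
entries are replaced by their conditional expectation given the observed
stations on the same day; observed entries are never altered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import natural_cubic_basis

__all__ = [
    "StationSeries",
    "QCReport",
    "aggregate_hourly_to_daily",
    "qc_filter",
    "em_impute",
    "EmResult",
]

logger = logging.getLogger(__name__)


@dataclass
class StationSeries:
    """One station's dated daily observations. Missing values are NaN."""

    station_id: str
    x_km: float
    y_km: float
    calendar: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.calendar = pd.DatetimeIndex(self.calendar)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.calendar) != len(self.values):
            raise ValueError("calendar and values must have equal length")
        if len(self.calendar) > 1:
            deltas = np.diff(self.calendar.values).astype("timedelta64[D]")
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise ValueError("calendar must be consecutive daily dates")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("observed values must be finite")

    @property
    def mask(self) -> np.ndarray:
        """True where the day is missing."""
        return np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.mean()) if len(self.values) else 0.0


def aggregate_hourly_to_daily(
    hourly: pd.Series, min_hours: int = 18
) -> pd.Series:
    """Daily means from an hourly series indexed by timestamps.

    A day's value is the mean of its available hourly readings; days with
    fewer than ``min_hours`` readings are marked missing (NaN). Returns a
    series indexed by consecutive normalized dates spanning the input range;
    an empty input yields an empty series.
    """
    if hourly.empty:
        return pd.Series(dtype=float)
    idx = pd.DatetimeIndex(hourly.index)
    by_day = hourly.groupby(idx.normalize())
    means = by_day.mean()
    counts = by_day.count()
    means[counts < min_hours] = np.nan
    full = pd.date_range(means.index.min(), means.index.max(), freq="D")
    return means.reindex(full)


@dataclass
class QCReport:
    """Per-station missingness and the keep/drop decision."""

    per_year: pd.DataFrame  # rows: station_id, year, missing_fraction
    overall: pd.DataFrame  # rows: station_id, missing_fraction, kept

    def to_frame(self) -> pd.DataFrame:
        return self.overall.merge(
            self.per_year.pivot(index="station_id", columns="year",
                                values="missing_fraction"),
            on="station_id",
        )


def qc_filter(
    stations: list[StationSeries],
    max_year_missing: float = 0.20,
    max_overall_missing: float = 0.15,
) -> tuple[list[StationSeries], QCReport]:
    """Keep stations with acceptable missingness.

    A station is kept iff every calendar year's missing fraction is below
    ``max_year_missing`` (default 20%) AND the whole-period missing fraction
    is below ``max_overall_missing`` (default 15%).
    """
    if not stations:
        raise ValueError("qc_filter requires at least one station")
    per_year_rows = []
    overall_rows = []
    kept: list[StationSeries] = []
    for s in stations:
        years = s.calendar.year
        mask = s.mask
        ok = True
        for y in np.unique(years):
            frac = float(mask[years == y].mean())
            per_year_rows.append(
                {"station_id": s.station_id, "year": int(y),
                 "missing_fraction": frac}
            )
            if frac >= max_year_missing:
                ok = False
        overall = s.missing_fraction
        if overall >= max_overall_missing:
            ok = False
        overall_rows.append(
            {"station_id": s.station_id, "missing_fraction": overall,
             "kept": ok}
        )
        if ok:
            kept.append(s)
    if not kept:
        raise ValueError(
            "all stations dropped by QC; no exposure estimation is possible"
        )
    report = QCReport(pd.DataFrame(per_year_rows), pd.DataFrame(overall_rows))
    return kept, report


@dataclass
class EmResult:
    """Completed station series plus EM diagnostics."""

    stations: list[StationSeries]
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))


def _time_spline_design(n_days: int, n_years: float, df_per_year: int) -> np.ndarray:
    """Natural-cubic trend/seasonality design over the day index.

    Total df = df_per_year * n_years columns (intercept included), knots at
    equally spaced quantiles of time with boundary knots at the series ends.
    """
    df = max(2, int(round(df_per_year * n_years)))
    df = min(df, max(2, n_days - 1))
    t = np.arange(n_days, dtype=float)
    knots = np.linspace(0.0, n_days - 1.0, df)
    return natural_cubic_basis(t, knots, include_intercept=True)


def _observed_loglik(X: np.ndarray, M: np.ndarray, mu: np.ndarray,
                     sigma: np.ndarray) -> float:
    """Observed-data log-likelihood under the MVN-around-spline model."""
    total = 0.0
    patterns = {}
    for t in range(X.shape[0]):
        key = M[t].tobytes()
        patterns.setdefault(key, []).append(t)
    for key, days in patterns.items():
        miss = np.frombuffer(key, dtype=bool)
        obs = ~miss
        if not obs.any():
            continue
        S = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(S)
        Sinv = np.linalg.inv(S)
        d = X[np.ix_(days, np.flatnonzero(obs))] - mu[np.ix_(days, np.flatnonzero(obs))]
        quad = np.einsum("ij,jk,ik->i", d, Sinv, d)
        k = int(obs.sum())
        total += float(
            -0.5 * (quad.sum() + len(days) * (logdet + k * np.log(2 * np.pi)))
        )
    return total


def em_impute(
    stations: list[StationSeries],
    df_per_year: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> EmResult:
    """Complete a multivariate daily station series by EM.

    Model: the cross-station daily vector is multivariate normal, station s's
    mean on day t being a natural-cubic-spline function of t with
    ``df_per_year`` degrees of freedom per year of data, and a free
    cross-station covariance capturing the spatial dependence that makes
    imputation informative. The E-step replaces missing entries by their
    conditional expectation given the day's observed entries; the M-step
    refits the spline coefficients (OLS per station — exact here because all
    stations share the same time design) and the covariance (including the
    conditional covariance of the imputed entries). Iteration stops when the
    largest absolute change in any imputed value falls below ``tol``.
    """
    if len(stations) < 2:
        raise ValueError("em_impute requires >= 2 stations")
    cal = stations[0].calendar
    for s in stations[1:]:
        if not s.calendar.equals(cal):
            raise ValueError("all stations must share one calendar")
    if any((~s.mask).sum() < 1 for s in stations):
        raise ValueError("every station needs at least one observed value")

    T = len(cal)
    S = len(stations)
    X = np.column_stack([s.values for s in stations])
    M = np.isnan(X)
    if not M.any():
        return EmResult([s for s in stations], True, 0)

    n_years = max(T / 365.25, 1.0 / 365.25)
    Z = _time_spline_design(T, n_years, df_per_year)
    ZtZinv_Zt = np.linalg.solve(Z.T @ Z, Z.T)

    # Start from per-station spline fits on the observed days.
    Xc = X.copy()
    for j in range(S):
        obs = ~M[:, j]
        beta = np.linalg.lstsq(Z[obs], X[obs, j], rcond=None)[0]
        Xc[M[:, j], j] = (Z @ beta)[M[:, j]]

    pattern_days: dict[bytes, np.ndarray] = {}
    for t in range(T):
        if M[t].any():
            pattern_days.setdefault(M[t].tobytes(), []).append(t)  # type: ignore[union-attr]
    pattern_days = {k: np.asarray(v) for k, v in pattern_days.items()}

    loglik_trace: list[float] = []
    converged = False
    A = ZtZinv_Zt @ Xc  # spline coefficients, one column per station
    mu = Z @ A
    resid = Xc - mu
    sigma = resid.T @ resid / T
    it = 0
    for it in range(1, max_iter + 1):
        loglik_trace.append(_observed_loglik(X, M, mu, sigma))
        # E-step: conditional means of missing entries + accumulated
        # conditional covariance for the M-step.
        Xe = X.copy()
        Xe[M] = 0.0
        Cacc = np.zeros((S, S))
        for key, days in pattern_days.items():
            miss = np.frombuffer(key, dtype=bool)
            obs = ~miss
            mi = np.flatnonzero(miss)
            oi = np.flatnonzero(obs)
            Soo = sigma[np.ix_(oi, oi)]
            trace_ridge = 1e-8 * np.trace(Soo) / max(len(oi), 1)
            if oi.size:
                try:
                    G = np.linalg.solve(Soo, sigma[np.ix_(oi, mi)])
                except np.linalg.LinAlgError:
                    Soo = Soo + trace_ridge * np.eye(len(oi))
                    G = np.linalg.solve(Soo, sigma[np.ix_(oi, mi)])
                cond = (
                    mu[np.ix_(days, mi)]
                    + (X[np.ix_(days, oi)] - mu[np.ix_(days, oi)]) @ G
                )
                C = sigma[np.ix_(mi, mi)] - sigma[np.ix_(mi, oi)] @ G
            else:  # whole day missing
                cond = mu[np.ix_(days, mi)]
                C = sigma[np.ix_(mi, mi)]
            Xe[np.ix_(days, mi)] = cond
            Cacc[np.ix_(mi, mi)] += len(days) * C
        # M-step
        A = ZtZinv_Zt @ Xe
        mu = Z @ A
        resid = Xe - mu
        sigma = (resid.T @ resid + Cacc) / T
        d = np.abs(np.diag(sigma))
        if np.linalg.matrix_rank(sigma) < S or np.min(d) < 1e-12:
            sigma = sigma + (1e-8 * np.trace(sigma) / S) * np.eye(S)
        delta = float(np.max(np.abs(Xe[M] - Xc[M])))
        Xc = Xe
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM imputation did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    loglik_trace.append(_observed_loglik(X, M, mu, sigma))

    out = []
    for j, s in enumerate(stations):
        vals = X[:, j].copy()
        vals[M[:, j]] = Xc[M[:, j], j]
        out.append(
            StationSeries(s.station_id, s.x_km, s.y_km, cal, vals)
        )
    return EmResult(out, converged, it, np.asarray(loglik_trace))
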