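"""Percentile-based heat-wave definition and run-length detection.

A heat wave is defined per subject: the threshold is a high percentile (90th
to 99th) of that subject's own hot-season daily mean temperature pooled over
the study years, and a heat-wave day is a day whose temperature strictly
exceeds the threshold AND belongs to a run of at least ``min_duration``
(default 2) consecutive exceedance days. Days outside the hot season never
count as exceedances, so a run cannot bridge the off-season boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeatwaveDefinition",
    "HeatwaveIndicator",
    "hot_season_mask",
    "individual_threshold",
    "detect",
    "flag_runs",
    "threshold_matrix",
    "mean_threshold_table",
    "DEFAULT_PERCENTILES",
    "DEFAULT_HOT_SEASON_MONTHS",
]

DEFAULT_PERCENTILES = (90.0, 92.5, 95.0, 97.5, 99.0)
DEFAULT_HOT_SEASON_MONTHS = frozenset({11, 12, 1, 2, 3})


@dataclass(frozen=True)
class HeatwaveDefinition:
    """A percentile threshold plus a minimum duration in days."""

    percentile: float = 90.0
    min_duration_days: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.min_duration_days < 1:
            raise ValueError("min duration must be >= 1")


@dataclass
class HeatwaveIndicator:
    """Daily heat-wave flags for one subject, with the threshold used."""

    subject_id: str
    calendar: pd.DatetimeIndex
    flags: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        """One row per day: subject, date, flag, threshold (for export)."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "date": pd.DatetimeIndex(self.calendar),
                "heatwave": np.asarray(self.flags).astype(int),
                "threshold_degc": self.threshold,
            }
        )


def hot_season_mask(
    calendar: pd.DatetimeIndex, months=DEFAULT_HOT_SEASON_MONTHS
) -> np.ndarray:
    """Boolean mask of days whose month belongs to the hot season."""
    return np.isin(pd.DatetimeIndex(calendar).month, sorted(months))


def individual_threshold(
    values: np.ndarray,
    hot_mask: np.ndarray,
    percentile: float,
    min_days: int = 30,
) -> float:
    """Hot-season temperature percentile for one subject.

    Empirical quantile with linear interpolation between order statistics
    (interpolating at rank 1 + (n-1)p), pooled over all study years'
    hot-season days.
    """
    vals = np.asarray(values, dtype=float)[np.asarray(hot_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_days:
        raise ValueError(
            f"only {vals.size} hot-season days available (need >= {min_days})"
        )
    return float(np.quantile(vals, percentile / 100.0, method="linear"))


def flag_runs(exceed: np.ndarray, min_duration: int = 2) -> np.ndarray:
    """Keep only exceedance days in runs of >= min_duration consecutive days.

    Works on a boolean vector or a (series x days) matrix; runs are counted
    along the last axis.
    """
    e = np.atleast_2d(np.asarray(exceed, dtype=bool))
    n = e.shape[1]
    if min_duration == 2 and n >= 2:
        # a day is in a >=2-run iff it exceeds and a neighbor does too
        prev = np.zeros_like(e)
        prev[:, 1:] = e[:, :-1]
        nxt = np.zeros_like(e)
        nxt[:, :-1] = e[:, 1:]
        out = e & (prev | nxt)
        return out[0] if np.asarray(exceed).ndim == 1 else out
    # forward pass: length of the run ending at t
    run = np.zeros(e.shape, dtype=np.int32)
    run[:, 0] = e[:, 0]
    for t in range(1, n):
        run[:, t] = np.where(e[:, t], run[:, t - 1] + 1, 0)
    # backward pass: propagate each run's final length to all its days
    full = run.copy()
    for t in range(n - 2, -1, -1):
        cont = e[:, t] & e[:, t + 1]
        full[:, t] = np.where(cont, full[:, t + 1], full[:, t])
    out = e & (full >= min_duration)
    return out[0] if np.asarray(exceed).ndim == 1 else out


def detect(
    values: np.ndarray,
    threshold: float,
    hot_mask: np.ndarray | None = None,
    min_duration: int = 2,
) -> np.ndarray:
    """Daily heat-wave flags: strict exceedance in runs of >= min_duration.

    ``hot_mask`` restricts exceedance to hot-season days; a run interrupted
    by the off-season boundary does not bridge across it.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.asarray(values, dtype=float)
    exceed = vals > threshold
    if hot_mask is not None:
        exceed = exceed & np.asarray(hot_mask, dtype=bool)
    return flag_runs(exceed, min_duration)


def threshold_matrix(
    values: np.ndarray, hot_mask: np.ndarray, percentile: float,
    min_days: int = 30,
) -> np.ndarray:
    """Per-row hot-season percentile for a (subjects x days) matrix."""
    vals = np.asarray(values, dtype=float)[:, np.asarray(hot_mask, dtype=bool)]
    if vals.shape[1] < min_days:
        raise ValueError("insufficient hot-season days")
    return np.quantile(vals, percentile / 100.0, axis=1, method="linear")


def mean_threshold_table(
    values: np.ndarray,
    hot_mask: np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Mean (and sd) of per-subject thresholds for each percentile definition."""
    rows = []
    for p in percentiles:
        thr = threshold_matrix(values, hot_mask, p)
        rows.append(
            {"percentile": p, "mean_threshold": float(thr.mean()),
             "sd_threshold": float(thr.std(ddof=1)) if thr.size > 1 else 0.0}
        )
    return pd.DataFrame(rows)
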