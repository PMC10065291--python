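"""Time-stratified case-crossover design construction.

Each death contributes one matched set (stratum): the case day plus its
referent days — every other day in the same calendar month and year that
falls on the same weekday. Self-matching removes time-invariant confounding;
the time-stratified referent rule removes day-of-week, seasonal and
long-term-trend confounding by design. Each stratum day carries the lagged
heat-wave indicator vector and lagged absolute-humidity vector needed by the
distributed-lag model, plus a public-holiday flag.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["select_referents", "build_strata", "StrataData"]


def select_referents(case_day: dt.date) -> list[dt.date]:
    """All same-weekday days in the case day's month and year, case excluded.

    Returns 3 or 4 dates, sorted ascending (a weekday occurs 4 or 5 times in
    a month). Referent selection is symmetric: the case day is a referent of
    each of its referents.
    """
    if isinstance(case_day, (pd.Timestamp, dt.datetime)):
        case_day = case_day.date()
    first = ((case_day.day - 1) % 7) + 1
    if case_day.month == 12:
        month_days = 31
    else:
        month_days = (
            dt.date(case_day.year, case_day.month + 1, 1) - dt.timedelta(days=1)
        ).day
    out = []
    for dom in range(first, month_days + 1, 7):
        if dom != case_day.day:
            out.append(dt.date(case_day.year, case_day.month, dom))
    return out


@dataclass
class StrataData:
    """Flattened matched sets ready for conditional-logistic fitting.

    One row per stratum day; rows of a stratum are contiguous and ordered by
    date. ``lagged_hw[i, l]`` is the heat-wave indicator l days before row
    i's date (analogously ``lagged_ah``).
    """

    stratum_id: np.ndarray
    death_id: np.ndarray
    day_index: np.ndarray
    is_case: np.ndarray
    lagged_hw: np.ndarray
    lagged_ah: np.ndarray
    holiday: np.ndarray
    n_excluded: int
    n_deaths_used: int
    lagged_tmean: np.ndarray | None = None

    @property
    def n_strata(self) -> int:
        return int(np.unique(self.stratum_id).size)

    def to_frame(self, calendar: pd.DatetimeIndex | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "stratum_id": self.stratum_id,
                "death_id": self.death_id,
                "is_case": self.is_case.astype(int),
                "holiday": self.holiday.astype(int),
            }
        )
        if calendar is not None:
            df.insert(2, "date", pd.DatetimeIndex(calendar)[self.day_index])
        for l in range(self.lagged_hw.shape[1]):
            df[f"hw_lag{l}"] = self.lagged_hw[:, l]
        for l in range(self.lagged_ah.shape[1]):
            df[f"ah_lag{l}"] = self.lagged_ah[:, l]
        return df


def build_strata(
    deaths: pd.DataFrame,
    hw: np.ndarray,
    ah: np.ndarray,
    calendar: pd.DatetimeIndex,
    L: int,
    holidays: set | None = None,
    hot_season_months: set | frozenset | None = None,
    tmean: np.ndarray | None = None,
) -> StrataData:
    """Build matched sets with complete lag vectors.

    Parameters
    ----------
    deaths : DataFrame
        Columns ``death_id``, ``subject_index`` (row into ``hw``/``ah``) and
        ``date``.
    hw, ah : (subjects x days) arrays
        Per-subject daily heat-wave indicator and absolute humidity on
        ``calendar``.
    L : int
        Lag length; every stratum day needs exposure back to day - L.
    holidays : set of dates, optional
    hot_season_months : set of month numbers, optional
        Deaths outside these months are dropped (not counted as lag
        exclusions).

    Deaths whose case day or any referent day would need exposure before the
    calendar start (day index < L) are excluded and counted, mirroring the
    usual first-study-days exclusion of lagged designs.
    """
    if deaths.empty:
        raise ValueError("no deaths supplied")
    dates = pd.DatetimeIndex(deaths["date"])
    if hot_season_months is not None:
        in_season = np.isin(dates.month, sorted(hot_season_months))
        deaths = deaths.loc[in_season].reset_index(drop=True)
        dates = pd.DatetimeIndex(deaths["date"])
        if deaths.empty:
            raise ValueError("no deaths inside the hot season")

    day_pos = pd.Series(np.arange(len(calendar)), index=calendar)
    case_idx = day_pos.reindex(dates).to_numpy()
    if np.isnan(case_idx).any():
        raise ValueError("death dates outside the exposure calendar")
    case_idx = case_idx.astype(int)

    dom = dates.day.to_numpy()
    month_len = dates.days_in_month.to_numpy()
    first_dom = ((dom - 1) % 7) + 1
    # up to 5 same-weekday days per month
    cand_dom = first_dom[:, None] + 7 * np.arange(5)[None, :]
    valid = cand_dom <= month_len[:, None]
    cand_idx = case_idx[:, None] + (cand_dom - dom[:, None])
    cand_idx = np.where(valid, cand_idx, -1)

    min_idx = np.where(valid, cand_idx, np.iinfo(int).max).min(axis=1)
    max_idx = cand_idx.max(axis=1)
    keep = (min_idx >= L) & (max_idx < len(calendar))
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("every death excluded by the lag-completeness rule")

    deaths_k = deaths.loc[keep].reset_index(drop=True)
    cand_idx = cand_idx[keep]
    valid = valid[keep]
    case_idx = case_idx[keep]
    subj = deaths_k["subject_index"].to_numpy()

    sizes = valid.sum(axis=1)
    stratum_id = np.repeat(np.arange(len(deaths_k)), sizes)
    death_id = np.repeat(deaths_k["death_id"].to_numpy(), sizes)
    flat_idx = cand_idx[valid]
    subj_rows = np.repeat(subj, sizes)
    is_case = flat_idx == np.repeat(case_idx, sizes)

    lag_offsets = np.arange(L + 1)
    gather = flat_idx[:, None] - lag_offsets[None, :]
    lagged_hw = hw[subj_rows[:, None], gather].astype(float)
    lagged_ah = ah[subj_rows[:, None], gather].astype(float)
    lagged_tmean = (
        tmean[subj_rows[:, None], gather].astype(float)
        if tmean is not None else None
    )

    if holidays:
        hol_days = np.zeros(len(calendar), dtype=bool)
        hol_set = {pd.Timestamp(h) for h in holidays}
        hol_days[[i for i, d in enumerate(calendar) if d in hol_set]] = True
        holiday = hol_days[flat_idx]
    else:
        holiday = np.zeros(flat_idx.size, dtype=bool)

    return StrataData(
        stratum_id=stratum_id,
        death_id=death_id,
        day_index=flat_idx,
        is_case=is_case,
        lagged_hw=lagged_hw,
        lagged_ah=lagged_ah,
        holiday=holiday,
        n_excluded=n_excluded,
        n_deaths_used=len(deaths_k),
        lagged_tmean=lagged_tmean,
    )
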