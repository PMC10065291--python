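"""Delimited-text readers and writers for the pipeline's data products."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GroundTruth
from .weather import StationSeries

__all__ = [
    "write_stations",
    "read_stations",
    "write_deaths",
    "read_deaths",
    "write_ground_truth",
    "read_ground_truth",
    "read_holidays",
    "write_holidays",
]


def write_stations(stations: list[StationSeries], path: str | Path) -> None:
    """One row per station-day: station_id, x_km, y_km, date, value."""
    frames = [
        pd.DataFrame(
            {
                "station_id": s.station_id,
                "x_km": s.x_km,
                "y_km": s.y_km,
                "date": s.calendar.strftime("%Y-%m-%d"),
                "value": s.values,
            }
        )
        for s in stations
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stations(path: str | Path) -> list[StationSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for sid, g in df.groupby("station_id", sort=True):
        g = g.sort_values("date")
        out.append(
            StationSeries(
                str(sid),
                float(g["x_km"].iloc[0]),
                float(g["y_km"].iloc[0]),
                pd.DatetimeIndex(g["date"]),
                g["value"].to_numpy(dtype=float),
            )
        )
    return out


def write_deaths(deaths: pd.DataFrame, path: str | Path) -> None:
    out = deaths.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_deaths(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Config-format sidecar with the injected effect (indicators excluded)."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "true_cum_log_or": float(gt.true_cum_log_or),
                "true_or": gt.true_or,
                "lag_weights": [float(w) for w in gt.lag_weights],
            },
            fh,
        )


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_holidays(holidays, path: str | Path) -> None:
    days = sorted(pd.Timestamp(h) for h in holidays)
    Path(path).write_text("\n".join(d.strftime("%Y-%m-%d") for d in days) + "\n")


def read_holidays(path: str | Path) -> set:
    text = Path(path).read_text().split()
    return {pd.Timestamp(t) for t in text if t.strip()}
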