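"""Individual-level exposure estimation from a station network.

Daily mean temperature and relative humidity at each subject's residence are
estimated by inverse distance weighting (IDW) from the monitoring stations.
IDW parameters (distance power, number of neighbors, search radius) are
selected by leave-one-out cross-validation over the station network,
minimizing RMSE. The selected interpolator is evaluated either directly at
the residence or — matching the gridded workflow — on a 1 km lattice whose
cell values are then averaged inside a 1 km buffer around the residence.
Absolute humidity (g/m^3) is derived from temperature and relative humidity
via the Magnus saturation-vapor-pressure formula.

Coordinates are planar kilometres. For geographic inputs use
:func:`project_lonlat` first (equirectangular about the domain centroid —
sub-metre error at city scale).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IdwParams",
    "CvScore",
    "ExposureSeries",
    "project_lonlat",
    "idw_predict",
    "idw_matrix",
    "loocv_select",
    "grid_interpolate",
    "buffer_average",
    "absolute_humidity",
    "DEFAULT_POWERS",
]

logger = logging.getLogger(__name__)

DEFAULT_POWERS = (1.0, 1.5, 2.0, 2.5, 3.0)
_COINCIDENT_KM = 1e-9
_EARTH_RADIUS_KM = 6371.0


class NoNeighborError(ValueError):
    """No station with an observed value inside the search radius."""


@dataclass(frozen=True)
class IdwParams:
    """Inverse-distance-weighting parameters."""

    power: float = 2.0
    n_neighbors: int = 13
    search_radius_km: float = np.inf

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.search_radius_km <= 0:
            raise ValueError("search radius must be positive")


@dataclass(frozen=True)
class CvScore:
    """Cross-validation score for one parameter combination."""

    params: IdwParams
    rmse: float
    mae: float

    def __post_init__(self) -> None:
        if np.isfinite(self.rmse) and self.rmse + 1e-12 < self.mae:
            raise ValueError("rmse must be >= mae")


@dataclass
class ExposureSeries:
    """Per-subject daily exposures over the study calendar."""

    subject_id: str
    calendar: pd.DatetimeIndex
    tmean: np.ndarray
    rh: np.ndarray
    ah: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "date": self.calendar,
                "tmean": self.tmean,
                "rh": self.rh,
                "ah": self.ah,
            }
        )


def project_lonlat(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Equirectangular projection to planar km about the point-set centroid."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = lon.mean(), lat.mean()
    x = np.deg2rad(lon - lon0) * _EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))
    y = np.deg2rad(lat - lat0) * _EARTH_RADIUS_KM
    return np.column_stack([x, y])


def idw_matrix(
    targets: np.ndarray, stations: np.ndarray, params: IdwParams
) -> np.ndarray:
    """Row-stochastic weight matrix mapping station values to target points.

    Row i holds the IDW weights of the ``k`` nearest in-radius stations for
    target i (zero elsewhere). A target coinciding with a station (distance
    < 1e-9 km) gets weight 1 on that station. Raises
    :class:`NoNeighborError` if some target has no station in radius.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    stations = np.atleast_2d(np.asarray(stations, dtype=float))
    d = np.sqrt(
        ((targets[:, None, :] - stations[None, :, :]) ** 2).sum(axis=2)
    )
    n_t, n_s = d.shape
    W = np.zeros((n_t, n_s))
    in_radius = d <= params.search_radius_km
    if not in_radius.any(axis=1).all():
        bad = int(np.flatnonzero(~in_radius.any(axis=1))[0])
        raise NoNeighborError(
            f"no station within {params.search_radius_km} km of target "
            f"{tuple(targets[bad])}"
        )
    k = min(params.n_neighbors, n_s)
    order = np.argsort(d, axis=1, kind="stable")
    rows = np.arange(n_t)[:, None]
    nearest = order[:, :k]
    dn = d[rows, nearest]
    use = dn <= params.search_radius_km
    coincident = dn < _COINCIDENT_KM
    with np.errstate(divide="ignore"):
        w = np.where(use, dn ** -params.power, 0.0)
    has_coincident = coincident.any(axis=1)
    w[has_coincident] = np.where(coincident[has_coincident], 1.0, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    W[rows, nearest] = w
    return W


def idw_predict(
    target: np.ndarray,
    stations: np.ndarray,
    values: np.ndarray,
    params: IdwParams,
) -> float | np.ndarray:
    """IDW prediction at one target point.

    ``values`` may be one value per station (returns a scalar) or a
    (stations x days) matrix (returns one prediction per day). The result is
    a convex combination of the k nearest in-radius station values; if the
    target coincides with a station, that station's value is returned.
    """
    W = idw_matrix(np.atleast_2d(target), stations, params)
    out = W @ np.asarray(values, dtype=float)
    return float(out[0]) if out.ndim == 1 or out.shape == (1,) else out[0]


def loocv_select(
    stations: np.ndarray,
    values: np.ndarray,
    powers: tuple[float, ...] = DEFAULT_POWERS,
    n_neighbors: tuple[int, ...] | None = None,
    radii: tuple[float, ...] = (np.inf,),
) -> tuple[IdwParams, pd.DataFrame]:
    """Leave-one-out selection of IDW parameters minimizing RMSE.

    Each station-day is predicted from the other stations for every
    combination of power, neighbor count and search radius; the combination
    with the smallest RMSE wins, ties broken by smaller power then smaller
    neighbor count. Returns the winning parameters and the full score table
    (power, n_neighbors, radius, rmse, mae).
    """
    stations = np.atleast_2d(np.asarray(stations, dtype=float))
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n_s = stations.shape[0]
    if n_s < 3:
        raise ValueError("loocv_select requires >= 3 stations")
    if n_neighbors is None:
        n_neighbors = tuple(range(1, n_s + 1))
    rows = []
    best: tuple[float, float, int, float] | None = None  # rmse, p, k, r
    for p, k, r in itertools.product(powers, n_neighbors, radii):
        params = IdwParams(p, k, r)
        errs = []
        for i in range(n_s):
            others = np.delete(np.arange(n_s), i)
            try:
                W = idw_matrix(stations[i : i + 1], stations[others], params)
            except NoNeighborError:
                errs = None
                break
            pred = (W @ values[others]).ravel()
            errs.append(pred - values[i])
        if errs is None:
            rmse, mae = np.inf, np.inf
        else:
            e = np.concatenate(errs)
            e = e[np.isfinite(e)]
            if e.size == 0:
                rmse, mae = np.inf, np.inf
            else:
                rmse = float(np.sqrt(np.mean(e ** 2)))
                mae = float(np.mean(np.abs(e)))
        rows.append(
            {"power": p, "n_neighbors": k, "search_radius_km": r,
             "rmse": rmse, "mae": mae}
        )
        key = (rmse, p, k, r if np.isfinite(r) else np.inf)
        if best is None or key < best:
            best = key
    assert best is not None
    params = IdwParams(best[1], best[2], best[3])
    return params, pd.DataFrame(rows)


def grid_interpolate(
    stations: np.ndarray,
    values: np.ndarray,
    params: IdwParams,
    bbox: tuple[float, float, float, float] | None = None,
    cell_km: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """IDW field on a regular lattice of cell centers covering the bbox.

    ``bbox`` is (xmin, ymin, xmax, ymax); default the station bounding box.
    Returns (cell centers (n x 2), predicted values) — for a (stations x
    days) value matrix the predictions are (cells x days).
    """
    stations = np.atleast_2d(np.asarray(stations, dtype=float))
    if bbox is None:
        bbox = (
            stations[:, 0].min(), stations[:, 1].min(),
            stations[:, 0].max(), stations[:, 1].max(),
        )
    xs = np.arange(bbox[0] + cell_km / 2, bbox[2] + cell_km / 2, cell_km)
    ys = np.arange(bbox[1] + cell_km / 2, bbox[3] + cell_km / 2, cell_km)
    if xs.size == 0:
        xs = np.array([(bbox[0] + bbox[2]) / 2])
    if ys.size == 0:
        ys = np.array([(bbox[1] + bbox[3]) / 2])
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    W = idw_matrix(centers, stations, params)
    return centers, W @ np.asarray(values, dtype=float)


def buffer_average(
    point: np.ndarray,
    cell_centers: np.ndarray,
    field: np.ndarray,
    radius_km: float = 1.0,
    stations: np.ndarray | None = None,
    station_values: np.ndarray | None = None,
    params: IdwParams | None = None,
) -> float | np.ndarray:
    """Mean of grid-cell values whose centers fall within the buffer.

    If no cell center lies inside the buffer the value falls back to a
    direct IDW prediction at the point (requires stations/values/params),
    which is logged.
    """
    point = np.asarray(point, dtype=float).ravel()
    cell_centers = np.atleast_2d(cell_centers)
    d = np.sqrt(((cell_centers - point) ** 2).sum(axis=1))
    inside = d <= radius_km
    if inside.any():
        vals = np.asarray(field, dtype=float)[inside]
        return vals.mean(axis=0)
    if stations is None or station_values is None or params is None:
        raise NoNeighborError(
            f"no grid cell within {radius_km} km of {tuple(point)} and no "
            "fallback stations supplied"
        )
    logger.info(
        "buffer at %s empty; falling back to point IDW", tuple(point)
    )
    return idw_predict(point, stations, station_values, params)


def absolute_humidity(t: np.ndarray, rh: np.ndarray) -> np.ndarray:
    """Absolute humidity (g/m^3) from temperature (degC) and RH (%).

    Magnus form: saturation vapor pressure
    ``es = 6.112 * exp(17.62 T / (243.12 + T))`` hPa, actual vapor pressure
    ``e = RH/100 * es``, and AH = 216.7 e / (273.15 + T). Monotone
    increasing in both arguments over the admissible range.
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((t < -20) | (t > 60)):
        raise ValueError("temperature out of range [-20, 60] degC")
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity out of range [0, 100] %")
    es = 6.112 * np.exp(17.62 * t / (243.12 + t))
    out = 216.7 * (rh / 100.0 * es) / (273.15 + t)
    return out if out.shape else float(out)
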