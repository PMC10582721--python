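"""Circle-regression + inverse-distance-weighting interpolation of onsets.

The national weather service's scheme is reproduced: the extent is tiled
with overlapping circles of radius 1.95 deg whose centers sit 1.95 deg
apart on a regular lattice; inside each circle an ordinary least-squares
model

    DOY = a0 + a1*h + a2*lon + a3*lat

is fitted to the member stations (h = elevation in m); the coefficient
vectors, attributed to the circle centers, are then blended per raster
cell by inverse distance weighting over the surrounding circles. Cells
above 1,000 m asl are masked.

Circle membership and IDW distances are computed in plain (lon, lat)
degree space, matching the scheme's degree-based circle geometry;
station-to-anchor distances elsewhere in the pipeline stay metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ElevationGrid, PhenoMap
from .onset import OnsetEstimate

__all__ = [
    "CircleGrid",
    "CircleModel",
    "InterpolationConfig",
    "make_circle_grid",
    "fit_circle_models",
    "predict_at_points",
    "idw_interpolate",
    "interpolate",
]


@dataclass(frozen=True)
class InterpolationConfig:
    spacing_deg: float = 1.95
    radius_deg: float = 1.95
    idw_power: float = 2.0
    min_stations_per_circle: int = 4
    mask_above_m: float = 1000.0
    neighborhood_factor: float = 2.0
    """A cell's "surrounding" circles are those within
    neighborhood_factor * radius_deg of it; if none, the nearest valid
    circle is used, which bounds the abrupt-boundary artifact of the
    scheme while guaranteeing a value everywhere."""
    center_eps_deg: float = 1e-9


@dataclass(frozen=True)
class CircleGrid:
    """Regular lattice of overlapping regression circles."""

    center_lats: np.ndarray
    center_lons: np.ndarray
    spacing_deg: float
    radius_deg: float
    extent: tuple[float, float, float, float]

    @property
    def n_circles(self) -> int:
        return len(self.center_lats)

    @property
    def shape(self) -> tuple[int, int]:
        """(n latitude rows, n longitude columns) of the lattice."""
        return (len(np.unique(self.center_lats)), len(np.unique(self.center_lons)))


@dataclass
class CircleModel:
    """OLS coefficients of one regression circle."""

    center_lat: float
    center_lon: float
    a0: float = np.nan
    a1: float = np.nan
    a2: float = np.nan
    a3: float = np.nan
    n_stations: int = 0
    valid: bool = False

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3])


def make_circle_grid(
    extent: tuple[float, float, float, float],
    spacing_deg: float = 1.95,
    radius_deg: float = 1.95,
) -> CircleGrid:
    """Tile an extent (lat_min, lat_max, lon_min, lon_max) with circles.

    Per axis the centers sit at ``min + k * spacing`` for
    ``k = 0 .. ceil(span / spacing)``; the national extent with the
    1.95 deg spacing yields a 5 x 6 lattice of 30 circles.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    if lat_max < lat_min or lon_max < lon_min:
        raise ValueError("invalid extent: negative span")
    if spacing_deg <= 0 or radius_deg <= 0:
        raise ValueError("spacing and radius must be positive")
    if spacing_deg > 2 * radius_deg:
        raise ValueError("spacing must not exceed twice the radius (coverage)")

    def axis_centers(lo: float, hi: float) -> np.ndarray:
        span = hi - lo
        if span < 0:
            raise ValueError("degenerate extent: negative span")
        n = int(np.ceil(round(span / spacing_deg, 9)))
        return lo + spacing_deg * np.arange(n + 1)

    lats = axis_centers(lat_min, lat_max)
    lons = axis_centers(lon_min, lon_max)
    lon_g, lat_g = np.meshgrid(lons, lats)
    return CircleGrid(
        center_lats=lat_g.ravel(),
        center_lons=lon_g.ravel(),
        spacing_deg=spacing_deg,
        radius_deg=radius_deg,
        extent=tuple(extent),
    )


def _station_table(onsets: list[OnsetEstimate], stations: pd.DataFrame) -> pd.DataFrame:
    """Join onset estimates with station coordinates/elevations."""
    est = pd.DataFrame(
        {"station_id": [e.station_id for e in onsets], "doy_hat": [e.doy_hat for e in onsets]}
    )
    cols = stations[["station_id", "lat", "lon", "elev_m"]]
    merged = est.merge(cols, on="station_id", how="inner")
    if len(merged) < len(est):
        missing = set(est["station_id"]) - set(merged["station_id"])
        raise ValueError(f"stations without coordinates: {sorted(missing)[:5]} ...")
    # canonical order makes the fitted map invariant to input order
    return merged.sort_values("station_id", kind="stable").reset_index(drop=True)


def fit_circle_models(
    onsets: list[OnsetEstimate],
    stations: pd.DataFrame,
    grid: CircleGrid,
    min_stations: int = 4,
) -> list[CircleModel]:
    """Fit DOY ~ 1 + h + lon + lat by OLS within every circle.

    ``stations`` maps station_id to (lat, lon, elev_m). A station belongs
    to a circle when its Euclidean distance to the center in (lon, lat)
    degree space is at most the circle radius. Circles with fewer than
    ``min_stations`` members or a rank-deficient design are flagged
    invalid rather than raising.
    """
    tbl = _station_table(onsets, stations)
    lats = tbl["lat"].to_numpy()
    lons = tbl["lon"].to_numpy()
    X_full = np.column_stack(
        [np.ones(len(tbl)), tbl["elev_m"].to_numpy(), lons, lats]
    )
    y_full = tbl["doy_hat"].to_numpy()

    models: list[CircleModel] = []
    for c_lat, c_lon in zip(grid.center_lats, grid.center_lons):
        d2 = (lons - c_lon) ** 2 + (lats - c_lat) ** 2
        member = d2 <= grid.radius_deg**2
        m = CircleModel(center_lat=float(c_lat), center_lon=float(c_lon), n_stations=int(member.sum()))
        if m.n_stations >= min_stations:
            X, y = X_full[member], y_full[member]
            if np.linalg.matrix_rank(X) == 4:
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                if np.all(np.isfinite(coef)):
                    m.a0, m.a1, m.a2, m.a3 = (float(c) for c in coef)
                    m.valid = True
        models.append(m)
    return models


def predict_at_points(
    models: list[CircleModel],
    lats: np.ndarray,
    lons: np.ndarray,
    elevs: np.ndarray,
    config: InterpolationConfig = InterpolationConfig(),
) -> np.ndarray:
    """IDW-blend circle-model predictions at arbitrary points.

    For each point, every surrounding valid circle i contributes
    ``a0 + a1*h + a2*lon + a3*lat`` with weight ``d_i^(-power)`` where
    ``d_i`` is the degree-space distance to the circle center; a point
    closer than ``center_eps_deg`` to a center takes that circle's
    prediction exactly; a point with no surrounding circle falls back to
    the nearest valid one.
    """
    valid = [m for m in models if m.valid]
    if not valid:
        raise ValueError("no valid circle model; cannot interpolate")
    lats = np.asarray(lats, dtype=float).ravel()
    lons = np.asarray(lons, dtype=float).ravel()
    elevs = np.asarray(elevs, dtype=float).ravel()

    c_lat = np.array([m.center_lat for m in valid])
    c_lon = np.array([m.center_lon for m in valid])
    coefs = np.stack([m.coef for m in valid])  # (n_circles, 4)

    # predictions: (n_points, n_circles)
    design = np.column_stack([np.ones_like(lats), elevs, lons, lats])
    preds = design @ coefs.T
    dist = np.sqrt((lons[:, None] - c_lon[None, :]) ** 2 + (lats[:, None] - c_lat[None, :]) ** 2)

    out = np.empty(len(lats))
    near_r = config.neighborhood_factor * config.radius_deg
    surrounding = dist <= near_r
    # exact hit on a center
    at_center = dist < config.center_eps_deg
    hit = at_center.any(axis=1)
    nearest = np.argmin(dist, axis=1)

    with np.errstate(divide="ignore"):
        w = np.where(surrounding, dist, np.inf) ** (-config.idw_power)
    wsum = w.sum(axis=1)
    blended_ok = np.isfinite(wsum) & (wsum > 0)
    out[blended_ok] = (w[blended_ok] * preds[blended_ok]).sum(axis=1) / wsum[blended_ok]
    # no surrounding circle -> nearest valid circle
    out[~blended_ok] = preds[~blended_ok, nearest[~blended_ok]]
    # coincident with a center -> that circle exactly (overrides blending)
    out[hit] = preds[hit, np.argmax(at_center[hit], axis=1)]
    return out


def idw_interpolate(
    models: list[CircleModel],
    elevation: ElevationGrid,
    config: InterpolationConfig = InterpolationConfig(),
) -> PhenoMap:
    """Rasterize the blended circle predictions onto the elevation grid.

    Cells above ``mask_above_m`` (or with missing elevation) are masked
    and hold NaN.
    """
    lat_g, lon_g = elevation.cell_centers()
    elev = elevation.values
    mask = ~np.isfinite(elev) | (elev > config.mask_above_m)
    values = np.full(elev.shape, np.nan)
    if (~mask).any():
        values[~mask] = predict_at_points(
            models, lat_g[~mask], lon_g[~mask], elev[~mask], config
        )
    return PhenoMap(grid=elevation, values=values, mask=mask, mask_above_m=config.mask_above_m)


def interpolate(
    onsets: list[OnsetEstimate],
    stations: pd.DataFrame,
    elevation: ElevationGrid,
    config: InterpolationConfig = InterpolationConfig(),
    extent: tuple[float, float, float, float] | None = None,
) -> PhenoMap:
    """Full chain: circle lattice -> per-circle OLS -> IDW raster."""
    if extent is None:
        extent = elevation.extent
    grid = make_circle_grid(extent, config.spacing_deg, config.radius_deg)
    models = fit_circle_models(onsets, stations, grid, config.min_stations_per_circle)
    return idw_interpolate(models, elevation, config)
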