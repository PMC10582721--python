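"""Synthetic phenology worlds: truth field, relief, reference network, records.

The generator emulates the two data sources the pipeline consumes — a
reference network of stations reporting onset-of-flowering day-of-year
(DOY), and streams of opportunistic presence-only observations whose
date density follows one of three archetypal curves (a single
flowering-linked peak, two peaks, or near-uniform background).

The true onset surface is a plane in (elevation, lon, lat) plus optional
smooth spatial noise, mirroring the regression form the interpolation
stage fits, so that parameter-recovery tests can be exact.

Quantile pinning
----------------
For peaked archetypes the flowering-linked date component is a
three-parameter Weibull whose location is solved in closed form, per
site, so that the CDF of the full date mixture evaluated at the local
true onset equals ``true_percentile`` exactly. The archetype's
``true_percentile`` is therefore known by construction, which is what
lets the percentile-calibration stage be tested against ground truth.
``onset_offset_days`` (default 0) shifts the whole flowering-linked
component afterwards and acts as a deliberate mis-calibration dial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .grids import ElevationGrid, write_ascii_grid

__all__ = [
    "TruthField",
    "SpeciesArchetype",
    "SimulationConfig",
    "SyntheticWorld",
    "generate_world",
    "generate_elevation",
    "sample_elevation",
    "write_world",
]

DOY_MIN, DOY_MAX = 1, 365


@dataclass(frozen=True)
class TruthField:
    """True onset surface: plane in (h, lon, lat) plus optional noise.

    ``b0`` is the intercept in days, ``b1`` days per metre elevation,
    ``b2``/``b3`` days per degree longitude/latitude.  ``spatial_noise_sd``
    scales a smooth random field (sum of random-phase sinusoids);
    ``nugget_sd`` is i.i.d. per-station noise added when anchors report.
    """

    b0: float = 100.0
    b1: float = 0.03
    b2: float = -1.2
    b3: float = 2.5
    spatial_noise_sd: float = 0.0
    nugget_sd: float = 0.0
    n_noise_waves: int = 8
    noise_wavelength_deg: float = 3.0

    def plane(self, lat, lon, elev_m):
        lat = np.asarray(lat, dtype=float)
        return self.b0 + self.b1 * np.asarray(elev_m, float) + self.b2 * np.asarray(lon, float) + self.b3 * lat

    def _noise(self, lat, lon, rng_key: int) -> np.ndarray:
        """Smooth zero-mean spatial noise, deterministic in ``rng_key``."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        if self.spatial_noise_sd == 0 or self.n_noise_waves == 0:
            return np.zeros(lat.shape)
        rng = np.random.default_rng(rng_key)
        k = 2 * np.pi / self.noise_wavelength_deg
        thetas = rng.uniform(0, 2 * np.pi, self.n_noise_waves)
        phases = rng.uniform(0, 2 * np.pi, self.n_noise_waves)
        waves = np.cos(
            k * (np.cos(thetas)[:, None] * lon.ravel() + np.sin(thetas)[:, None] * lat.ravel())
            + phases[:, None]
        )
        # sum of m unit cosines with random phase has sd sqrt(m/2)
        out = waves.sum(axis=0) * self.spatial_noise_sd / np.sqrt(self.n_noise_waves / 2)
        return out.reshape(lat.shape)

    def onset(self, lat, lon, elev_m, rng_key: int = 0):
        """True onset DOY at a location (noise-free if both sds are 0)."""
        return self.plane(lat, lon, elev_m) + self._noise(lat, lon, rng_key)


@dataclass(frozen=True)
class SpeciesArchetype:
    """Shape of a species' opportunistic observation-date density.

    ``curve_kind`` selects a single flowering-linked peak, a double peak
    (flowering plus a later, e.g. fruiting, peak), or pure uniform
    background.  ``background_fraction`` is the share of records unrelated
    to flowering, scattered uniformly over the year.  ``true_percentile``
    is the quantile of the generated date distribution that falls on the
    local true onset (pinned by construction; see module docstring).
    """

    name: str
    curve_kind: Literal["single_peak", "two_peak", "uniform"] = "single_peak"
    n_records: int = 5000
    true_percentile: float = 0.2
    peak_spread_days: float = 15.0
    onset_offset_days: float = 0.0
    background_fraction: float = 0.1
    peak_shape: float = 2.0
    second_peak_gap_days: float = 90.0
    second_peak_fraction: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if self.curve_kind == "uniform" and self.background_fraction != 1.0:
            object.__setattr__(self, "background_fraction", 1.0)
        if self.curve_kind != "uniform" and not 0 < self.true_percentile < 1:
            raise ValueError("true_percentile must lie in (0, 1)")
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")

    def _weibull_location(self, onset_doy: np.ndarray) -> np.ndarray:
        """Per-site Weibull location pinning mixture CDF(onset) = q.

        Solving bg*U(onset) + (1-bg)*w1*F_weib(onset; loc) = q for loc,
        where U is the uniform-background CDF on [1, 365] and w1 the
        weight of the flowering-linked (first) peak among non-background
        records (the second peak, if any, sits entirely after the onset).
        """
        q = self.true_percentile
        bg = self.background_fraction
        u = (np.asarray(onset_doy, float) - DOY_MIN) / (DOY_MAX - DOY_MIN)
        w1 = 1.0 if self.curve_kind == "single_peak" else 1.0 - self.second_peak_fraction
        p = (q - bg * u) / ((1.0 - bg) * w1)
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError(
                "true_percentile not reachable: background alone exceeds it "
                "(or leaves no mass) at some site; adjust background_fraction "
                "or true_percentile"
            )
        # F_weib(onset; loc, k, s) = 1 - exp(-((onset-loc)/s)^k) = p
        dist = self.peak_spread_days * (-np.log1p(-p)) ** (1.0 / self.peak_shape)
        return np.asarray(onset_doy, float) - dist

    def sample_doys(self, onset_doy, rng: np.random.Generator) -> np.ndarray:
        """Draw one observation DOY per entry of ``onset_doy``."""
        onset_doy = np.atleast_1d(np.asarray(onset_doy, dtype=float))
        n = onset_doy.size
        out = np.empty(n)
        u = rng.uniform(size=n)
        is_bg = u < self.background_fraction
        out[is_bg] = rng.uniform(DOY_MIN, DOY_MAX, is_bg.sum())
        n_fl = int((~is_bg).sum())
        if n_fl:
            loc = self._weibull_location(onset_doy[~is_bg])
            draws = loc + rng.weibull(self.peak_shape, n_fl) * self.peak_spread_days
            if self.curve_kind == "two_peak":
                second = rng.uniform(size=n_fl) < self.second_peak_fraction
                draws[second] = (
                    onset_doy[~is_bg][second]
                    + self.second_peak_gap_days
                    + rng.weibull(self.peak_shape, int(second.sum())) * self.peak_spread_days
                )
            out[~is_bg] = draws + self.onset_offset_days
        return np.clip(np.rint(out), DOY_MIN, DOY_MAX)


@dataclass(frozen=True)
class ReliefConfig:
    """Smooth deterministic relief: base + low-frequency sinusoids + ridge."""

    base_m: float = 250.0
    amplitude_m: float = 180.0
    wavelength_deg: float = 4.0
    ridge_amplitude_m: float = 0.0
    ridge_lon: float | None = None
    ridge_width_deg: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    extent: tuple[float, float, float, float] = (47.27, 55.06, 5.87, 15.04)
    """(lat_min, lat_max, lon_min, lon_max) in degrees."""
    cellsize_deg: float = 0.1
    relief: ReliefConfig = field(default_factory=ReliefConfig)
    truth: TruthField = field(default_factory=TruthField)
    n_anchors: int = 200
    species: tuple[SpeciesArchetype, ...] = (SpeciesArchetype(name="synthetica"),)
    years: tuple[int, ...] = (2020,)
    year_shift_days: float = 8.0
    """Added to the truth intercept for each year after the first."""
    round_onsets: bool = True
    cluster_fraction: float = 0.0
    cluster_centers: tuple[tuple[float, float], ...] = ()
    cluster_sd_deg: float = 0.3
    record_elevation_from_dem: bool = True

    def __post_init__(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.extent
        if lat_max <= lat_min or lon_max <= lon_min:
            raise ValueError("degenerate extent: zero or negative area")
        if self.n_anchors < 1:
            raise ValueError("n_anchors must be >= 1")
        if not self.species:
            raise ValueError("at least one species archetype required")

    def truth_for_year(self, year: int) -> TruthField:
        i = self.years.index(year)
        return replace(self.truth, b0=self.truth.b0 + i * self.year_shift_days)


@dataclass
class SyntheticWorld:
    config: SimulationConfig
    seed: int
    elevation: ElevationGrid
    anchors: pd.DataFrame
    """Columns: station_id, lat, lon, elev_m, species, year, onset_doy."""
    records: pd.DataFrame
    """Columns: record_id, species, year, lat, lon, elev_m, doy, date."""

    def true_onset(self, lat, lon, elev_m, year: int | None = None):
        year = year if year is not None else self.config.years[0]
        truth = self.config.truth_for_year(year)
        return truth.onset(lat, lon, elev_m, rng_key=self.seed)


def generate_elevation(config: SimulationConfig) -> ElevationGrid:
    """Deterministic smooth relief raster over the configured extent."""
    lat_min, lat_max, lon_min, lon_max = config.extent
    cs = config.cellsize_deg
    n_rows = max(1, int(np.ceil((lat_max - lat_min) / cs)))
    n_cols = max(1, int(np.ceil((lon_max - lon_min) / cs)))
    grid = ElevationGrid(xll=lon_min, yll=lat_min, cellsize=cs, values=np.zeros((n_rows, n_cols)))
    lat_g, lon_g = grid.cell_centers()
    grid.values[:] = _relief(lat_g, lon_g, config.relief)
    return grid


def _relief(lat, lon, relief: ReliefConfig) -> np.ndarray:
    k = 2 * np.pi / relief.wavelength_deg
    z = relief.base_m + relief.amplitude_m * (
        0.5 * np.sin(k * np.asarray(lon, float))
        + 0.3 * np.cos(k * 0.8 * np.asarray(lat, float))
        + 0.2 * np.sin(k * 0.5 * (np.asarray(lon, float) + np.asarray(lat, float)))
    )
    if relief.ridge_amplitude_m and relief.ridge_lon is not None:
        z = z + relief.ridge_amplitude_m * np.exp(
            -(((np.asarray(lon, float) - relief.ridge_lon) / relief.ridge_width_deg) ** 2)
        )
    return np.maximum(z, 0.0)


def sample_elevation(grid: ElevationGrid, lat, lon):
    """Elevation (m asl) of the grid cell containing each point."""
    return grid.sample(lat, lon)


def _sample_positions(n: int, config: SimulationConfig, rng: np.random.Generator):
    lat_min, lat_max, lon_min, lon_max = config.extent
    lats = rng.uniform(lat_min, lat_max, n)
    lons = rng.uniform(lon_min, lon_max, n)
    if config.cluster_fraction > 0 and config.cluster_centers:
        clustered = rng.uniform(size=n) < config.cluster_fraction
        idx = rng.integers(0, len(config.cluster_centers), int(clustered.sum()))
        centers = np.asarray(config.cluster_centers, dtype=float)
        lats[clustered] = np.clip(
            centers[idx, 0] + rng.normal(0, config.cluster_sd_deg, idx.size), lat_min, lat_max
        )
        lons[clustered] = np.clip(
            centers[idx, 1] + rng.normal(0, config.cluster_sd_deg, idx.size), lon_min, lon_max
        )
    return lats, lons


def generate_world(config: SimulationConfig, seed: int) -> SyntheticWorld:
    """Generate a complete synthetic world, deterministic in ``seed``."""
    master = np.random.SeedSequence(seed)
    anchor_rng, record_rng = (np.random.default_rng(s) for s in master.spawn(2))

    elevation = generate_elevation(config)

    a_lat, a_lon = _sample_positions(config.n_anchors, config, anchor_rng)
    a_elev = elevation.sample(a_lat, a_lon)

    anchor_rows = []
    for year in config.years:
        truth = config.truth_for_year(year)
        onset = truth.onset(a_lat, a_lon, a_elev, rng_key=seed)
        for sp in config.species:
            y_onset = onset + anchor_rng.normal(0, truth.nugget_sd, config.n_anchors) \
                if truth.nugget_sd > 0 else onset.copy()
            if config.round_onsets:
                y_onset = np.rint(y_onset)
            anchor_rows.append(
                pd.DataFrame(
                    {
                        "station_id": [f"A{i:04d}" for i in range(config.n_anchors)],
                        "lat": a_lat,
                        "lon": a_lon,
                        "elev_m": a_elev,
                        "species": sp.name,
                        "year": year,
                        "onset_doy": y_onset,
                    }
                )
            )
    anchors = pd.concat(anchor_rows, ignore_index=True)

    record_rows = []
    counter = 0
    for year in config.years:
        truth = config.truth_for_year(year)
        for sp in config.species:
            n = sp.n_records
            r_lat, r_lon = _sample_positions(n, config, record_rng)
            r_elev = (
                elevation.sample(r_lat, r_lon)
                if config.record_elevation_from_dem
                else _relief(r_lat, r_lon, config.relief)
            )
            local_onset = truth.onset(r_lat, r_lon, r_elev, rng_key=seed)
            doys = sp.sample_doys(local_onset, record_rng)
            record_rows.append(
                pd.DataFrame(
                    {
                        "record_id": [f"R{counter + i:07d}" for i in range(n)],
                        "species": sp.name,
                        "year": year,
                        "lat": r_lat,
                        "lon": r_lon,
                        "elev_m": r_elev,
                        "doy": doys.astype(int),
                    }
                )
            )
            counter += n
    records = pd.concat(record_rows, ignore_index=True)
    records["date"] = pd.to_datetime(
        records["year"] * 1000 + records["doy"], format="%Y%j"
    ).dt.strftime("%Y-%m-%d")

    return SyntheticWorld(
        config=config, seed=seed, elevation=elevation, anchors=anchors, records=records
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write records/anchors CSVs, the DEM and a config echo to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "anchors": out / "anchors.csv",
        "dem": out / "dem.asc",
        "config": out / "world.yaml",
    }
    world.records[["record_id", "species", "year", "lat", "lon", "elev_m", "doy", "date"]].to_csv(
        paths["records"], index=False
    )
    world.anchors.to_csv(paths["anchors"], index=False)
    write_ascii_grid(world.elevation, paths["dem"])
    cfg = world.config
    echo = {
        "seed": world.seed,
        "extent": list(cfg.extent),
        "cellsize_deg": cfg.cellsize_deg,
        "n_anchors": cfg.n_anchors,
        "years": list(cfg.years),
        "year_shift_days": cfg.year_shift_days,
        "round_onsets": cfg.round_onsets,
        "truth": {
            "b0": cfg.truth.b0,
            "b1": cfg.truth.b1,
            "b2": cfg.truth.b2,
            "b3": cfg.truth.b3,
            "spatial_noise_sd": cfg.truth.spatial_noise_sd,
            "nugget_sd": cfg.truth.nugget_sd,
        },
        "species": [
            {
                "name": sp.name,
                "curve_kind": sp.curve_kind,
                "n_records": sp.n_records,
                "true_percentile": sp.true_percentile,
                "peak_spread_days": sp.peak_spread_days,
                "background_fraction": sp.background_fraction,
                "onset_offset_days": sp.onset_offset_days,
            }
            for sp in cfg.species
        ],
    }
    paths["config"].write_text(yaml.safe_dump(echo, sort_keys=False))
    return paths
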