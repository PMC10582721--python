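import numpy as np
import pandas as pd
import pytest

from phenomap import (
    ElevationGrid,
    SimulationConfig,
    SpeciesArchetype,
    TruthField,
    generate_world,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact two-year synthetic world shared across read-only tests."""
    cfg = SimulationConfig(
        extent=(47.0, 50.0, 6.0, 10.0),
        cellsize_deg=0.1,
        n_anchors=80,
        species=(SpeciesArchetype(name="campanula", n_records=6000),),
        years=(2020, 2021),
        truth=TruthField(nugget_sd=1.0),
    )
    return generate_world(cfg, seed=11)


@pytest.fixture()
def flat_grid():
    """A constant 300 m elevation raster on a 0.5-degree grid."""
    return ElevationGrid(xll=6.0, yll=47.0, cellsize=0.5, values=np.full((6, 8), 300.0))


def make_records(lats, lons, elevs, doys, species="sp", year=2020, start=0):
    n = len(lats)
    return pd.DataFrame(
        {
            "record_id": [f"R{start + i:05d}" for i in range(n)],
            "species": species,
            "year": year,
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
            "elev_m": np.asarray(elevs, dtype=float),
            "doy": np.asarray(doys, dtype=int),
        }
    )


def make_anchor(lat=48.0, lon=8.0, elev_m=300.0, station_id="A0", **kw):
    return pd.Series({"station_id": station_id, "lat": lat, "lon": lon, "elev_m": elev_m, **kw})
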