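"""Shared study definition for the numbered analysis drivers.

One synthetic two-year world with three species archetypes spanning the
observation-curve patterns seen in opportunistic data: a clean
flowering-linked single peak, a double peak (flowering plus a later
fruiting-stage peak), and a near-uniform stream with no phenological
signal. Record counts sit inside the per-species range typical of a
national app-user stream (thousands to tens of thousands per year).
"""

from pathlib import Path

from phenomap import SimulationConfig, SpeciesArchetype, TruthField
from phenomap.interpolate import InterpolationConfig
from phenomap.pipeline import PipelineConfig
from phenomap.stations import StationParams

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20_20

SPECIES = (
    SpeciesArchetype(
        name="Synthetica unimodalis", curve_kind="single_peak",
        n_records=12_000, true_percentile=0.2, background_fraction=0.1,
    ),
    SpeciesArchetype(
        name="Synthetica bimodalis", curve_kind="two_peak",
        n_records=8_000, true_percentile=0.2, background_fraction=0.1,
    ),
    SpeciesArchetype(
        name="Synthetica uniformis", curve_kind="uniform",
        n_records=4_000, background_fraction=1.0,
    ),
)

SIMULATION = SimulationConfig(
    extent=(47.0, 52.0, 6.0, 12.0),
    cellsize_deg=0.1,  # ~10 km cells: desk-scale stand-in for the 1 km national DEM
    n_anchors=200,
    species=SPECIES,
    years=(2020, 2021),
    year_shift_days=8.0,
    truth=TruthField(b0=60.0, b1=0.03, b2=-1.2, b3=1.5, spatial_noise_sd=1.5, nugget_sd=1.5),
)

PIPELINE = PipelineConfig(
    simulation=SIMULATION,
    station_params=StationParams(),
    interpolation=InterpolationConfig(),
    n_boot=100,
    calibration_year=2020,
    min_virtual_stations=100,
)
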