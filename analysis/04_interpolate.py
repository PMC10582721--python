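"""Interpolate onset maps (circle regressions + IDW, 1000 m mask) for the
reference network and the virtual stations, both years."""

import numpy as np
import pandas as pd

from phenomap import OnsetEstimate, interpolate
from phenomap.grids import read_ascii_grid, write_ascii_grid, ElevationGrid
from phenomap.pipeline import reference_onsets

from study_config import PIPELINE, RESULTS, SIMULATION

records = pd.read_csv(RESULTS / "world" / "records.csv")
anchors = pd.read_csv(RESULTS / "world" / "anchors.csv")
dem = read_ascii_grid(RESULTS / "world" / "dem.asc")

out_dir = RESULTS / "maps"
out_dir.mkdir(parents=True, exist_ok=True)


def save(pheno, name):
    out = ElevationGrid(
        xll=dem.xll, yll=dem.yll, cellsize=dem.cellsize,
        values=np.where(pheno.mask, dem.nodata, pheno.values), nodata=dem.nodata,
    )
    write_ascii_grid(out, out_dir / f"{name}.asc")
    pheno.to_frame().to_csv(out_dir / f"{name}.csv", index=False)


made = 0
for sp in SIMULATION.species:
    slug = sp.name.replace(" ", "_")
    for year in SIMULATION.years:
        ref = reference_onsets(anchors, sp.name, year)
        ref_stations = anchors[(anchors.species == sp.name) & (anchors.year == year)]
        save(
            interpolate(ref, ref_stations, dem, PIPELINE.interpolation, extent=SIMULATION.extent),
            f"{slug}_{year}_reference",
        )
        onset_path = RESULTS / "onsets" / f"{slug}_{year}.csv"
        if not onset_path.exists():
            print(f"{sp.name} {year}: no calibrated onsets; opportunistic map skipped")
            continue
        est_df = pd.read_csv(onset_path)
        est = [
            OnsetEstimate(str(r.station_id), float(r.q), float(r.doy_hat), int(r.n))
            for r in est_df.itertuples()
        ]
        stations = pd.read_csv(RESULTS / "stations" / f"{slug}_{year}.csv")
        save(
            interpolate(est, stations, dem, PIPELINE.interpolation, extent=SIMULATION.extent),
            f"{slug}_{year}_opportunistic",
        )
        made += 2

print(f"{made + 0} interpolated maps -> {out_dir}")
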