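"""Evaluate map quality and cross-source agreement: station RMSE with the
20-day validity rule, map median/MAD per source and year, the
between-source median differences, and per-species cross-source
regressions."""

import numpy as np
import pandas as pd

from phenomap import (
    OnsetEstimate,
    classify_validity,
    cross_source_regression,
    interpolate,
    map_summary,
    predict_at_points,
    rmse,
)
from phenomap.grids import read_ascii_grid
from phenomap.interpolate import fit_circle_models, idw_interpolate, make_circle_grid
from phenomap.pipeline import reference_onsets

from study_config import PIPELINE, RESULTS, SIMULATION

records = pd.read_csv(RESULTS / "world" / "records.csv")
anchors = pd.read_csv(RESULTS / "world" / "anchors.csv")
dem = read_ascii_grid(RESULTS / "world" / "dem.asc")
circle_grid = make_circle_grid(SIMULATION.extent, PIPELINE.interpolation.spacing_deg,
                               PIPELINE.interpolation.radius_deg)

rows, cross_rows = [], []
for sp in SIMULATION.species:
    slug = sp.name.replace(" ", "_")
    for year in SIMULATION.years:
        per_source_pred = {}
        for source in ("reference", "opportunistic"):
            if source == "reference":
                est = reference_onsets(anchors, sp.name, year)
                stations = anchors[(anchors.species == sp.name) & (anchors.year == year)]
            else:
                onset_path = RESULTS / "onsets" / f"{slug}_{year}.csv"
                if not onset_path.exists():
                    continue
                df = pd.read_csv(onset_path)
                est = [
                    OnsetEstimate(str(r.station_id), float(r.q), float(r.doy_hat), int(r.n))
                    for r in df.itertuples()
                ]
                stations = pd.read_csv(RESULTS / "stations" / f"{slug}_{year}.csv")
            models = fit_circle_models(est, stations, circle_grid,
                                       PIPELINE.interpolation.min_stations_per_circle)
            pheno = idw_interpolate(models, dem, PIPELINE.interpolation)
            tbl = pd.DataFrame(
                {"station_id": [e.station_id for e in est], "doy": [e.doy_hat for e in est]}
            ).merge(stations[["station_id", "lat", "lon", "elev_m"]], on="station_id")
            pred = predict_at_points(models, tbl.lat.to_numpy(), tbl.lon.to_numpy(),
                                     tbl.elev_m.to_numpy(), PIPELINE.interpolation)
            value = rmse(tbl.doy.to_numpy(), pred)
            med, mad = map_summary(pheno)
            rows.append(
                {
                    "species": sp.name, "year": year, "source": source,
                    "rmse": round(value, 2), "validity": classify_validity(value),
                    "map_median": round(med, 1), "map_mad": round(mad, 1),
                    "n_stations": len(tbl),
                }
            )
            per_source_pred[source] = pd.DataFrame({"station_id": tbl.station_id, "doy": pred})
        if len(per_source_pred) == 2:
            fit = cross_source_regression(
                per_source_pred["reference"], per_source_pred["opportunistic"],
                species=sp.name, year=year,
            )
            cross_rows.append(
                {
                    "species": sp.name, "year": year, "slope": round(fit.slope, 3),
                    "intercept": round(fit.intercept, 2),
                    "r_squared": round(fit.r_squared, 3),
                    "n_shared_stations": fit.n_shared_stations,
                }
            )

report = pd.DataFrame(rows)
report.to_csv(RESULTS / "evaluation.csv", index=False)
cross = pd.DataFrame(cross_rows)
cross.to_csv(RESULTS / "cross_source.csv", index=False)

print(report.to_string(index=False))
print()
print(cross.to_string(index=False))

wide = report.pivot_table(index=["species", "year"], columns="source", values="map_median")
if "opportunistic" in wide:
    wide["median_diff"] = wide["opportunistic"] - wide["reference"]
    print("\nbetween-source map-median differences (days):")
    print(wide["median_diff"].dropna().round(1).to_string())
print(f"\nreports -> {RESULTS / 'evaluation.csv'}, {RESULTS / 'cross_source.csv'}")
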