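# phenomap

Flowering-onset maps from opportunistic plant observations.

National phenology networks map the onset of flowering — the day of
year (DOY) a species starts flowering — by interpolating dates reported
at fixed observer stations. Those networks are shrinking, while
plant-identification apps produce millions of *opportunistic* records:
species, location, date, but no phenophase. `phenomap` is a library and
analysis pipeline for turning such presence-only streams into onset
maps that are directly comparable to reference-network maps, for
ecologists and phenology-network operators who want to test or deploy
app data as a complement to trained observers.

## Method

The chain has four stages:

1. **Virtual stations.** Records of a species/year are matched to each
   reference station: qualifying records must lie within an expanding
   great-circle radius (5 km, +1 km steps, max 55 km) *and* within
   ±25 m asl of the station's elevation; the smallest radius with ≥ 35
   records forms a virtual station.
2. **Onset percentile.** A station's onset is a low quantile of its
   members' date distribution, estimated by fitting a two-parameter
   Weibull (shape k, scale λ) by maximum likelihood and applying the
   parametric-bootstrap reflection correction

       q̂_corrected = 2·λ̂(−ln(1−q))^(1/k̂) − mean(bootstrap quantiles).

3. **Percentile calibration.** The species-specific q* is the grid
   candidate whose interpolated map median best matches the reference
   map median in a designated calibration year; q* is then reused for
   all other years.
4. **Interpolation + evaluation.** Station onsets are interpolated with
   the reference scheme: overlapping circles of radius 1.95° on a 1.95°
   lattice, per-circle OLS `DOY = a0 + a1·h + a2·lon + a3·lat`, inverse-
   distance-weighted blending of circle predictions per raster cell,
   masking cells above 1,000 m asl. Maps are scored by station RMSE
   (≤ 20 d counts as low error), map median and MAD, between-source
   median differences and per-species cross-source regressions (R²).

A synthetic-world generator (truth surface, relief raster, reference
network, archetypal observation curves with a construction-known onset
percentile) makes every stage verifiable against ground truth. See
`docs/methods.md` for the full model description.

## Worked example

The numbered drivers under `analysis/` run a two-year synthetic study
with three species archetypes (clean single flowering peak, double
peak, uniform no-signal stream), 200 reference stations and
4,000–12,000 records per species-year:

```bash
python analysis/01_simulate.py
python analysis/02_build_stations.py
python analysis/03_calibrate_and_estimate.py
python analysis/04_interpolate.py
python analysis/05_evaluate.py
```

Calibration (year 2020) prints:

```
Synthetica unimodalis: q* = 0.41 (reference median 130.1, achieved 129.7)
Synthetica bimodalis:  q* = 0.25 (reference median 129.9, achieved 130.6)
Synthetica uniformis:  q* = 0.38 (reference median 130.2, achieved 129.6)
```

and the evaluation table (`results/evaluation.csv`) includes, among
its twelve species × year × source rows:

```
              species  year        source  rmse   validity  map_median  map_mad
Synthetica unimodalis  2021     reference  2.02  low_error       138.0      3.5
Synthetica unimodalis  2021 opportunistic  4.63  low_error       138.1      4.2
 Synthetica bimodalis  2021 opportunistic 10.95  low_error       137.4      3.5
 Synthetica uniformis  2020 opportunistic 21.41 high_error       129.6      5.9
 Synthetica uniformis  2021 opportunistic 19.38  low_error       131.1      4.3
```

Reading this: for the single-peak species the opportunistic map matches
the reference map (medians 138.1 vs 138.0 in the held-out year 2021,
RMSE well under the 20-day validity threshold, cross-source R² = 0.90);
the double-peak species still calibrates but with higher station error;
the uniform stream — dates unrelated to flowering — produces a
high-error map (RMSE 21.4 in 2020) and near-zero cross-source R², and
its calibrated percentile carries no phenological meaning. Note that
the calibrated q* (0.41) exceeds the construction percentile (0.2) even
for the single-peak species: its stream contains 10 % non-flowering
background records, whose distortion of the fitted Weibull is absorbed
by the calibration — the same mechanism that spreads calibrated
percentiles widely across real species.

The `phenomap` console command exposes the same stages
(`simulate`, `build-stations`, `estimate-onset`, `interpolate`,
`evaluate`, `run-all`) for file-based use.

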