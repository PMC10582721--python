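"""Quality metrics for interpolated phenology maps and source agreement.

Covers station RMSE with the <=20-day validity rule, map median / median
absolute deviation (MAD, unscaled day units), between-source median
differences, per-species cross-source regression with R^2, and kernel
density curves of observation dates over the year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import PhenoMap

__all__ = [
    "EvaluationReport",
    "CrossSourceFit",
    "rmse",
    "classify_validity",
    "map_summary",
    "compare_sources",
    "station_rmse",
    "cross_source_regression",
    "observation_density",
]

RMSE_THRESHOLD = 20.0


@dataclass(frozen=True)
class EvaluationReport:
    species: str
    year: int
    source: str  # "reference" or "opportunistic"
    rmse: float
    validity: str  # "low_error" / "high_error"
    map_median: float
    map_mad: float
    n_stations: int


@dataclass(frozen=True)
class CrossSourceFit:
    species: str
    year: int
    slope: float
    intercept: float
    r_squared: float
    n_shared_stations: int


def rmse(observed, predicted) -> float:
    """Root-mean-square error sqrt(sum((obs - pred)^2) / N)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size == 0:
        raise ValueError("RMSE of empty vectors is undefined")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def classify_validity(rmse_value: float, threshold: float = RMSE_THRESHOLD) -> str:
    """Interpolations with RMSE <= threshold (inclusive) count as low error."""
    return "low_error" if rmse_value <= threshold else "high_error"


def map_summary(pheno: PhenoMap) -> tuple[float, float]:
    """(median, MAD) over unmasked cells; MAD is unscaled, in days."""
    vals = pheno.unmasked_values
    if vals.size == 0:
        raise ValueError("map has no unmasked cells")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, mad


def compare_sources(map_a: PhenoMap, map_b: PhenoMap) -> float:
    """Difference of unmasked-cell medians, median(a) - median(b), in days."""
    return map_summary(map_a)[0] - map_summary(map_b)[0]


def station_rmse(observed_doys, predicted_doys, threshold: float = RMSE_THRESHOLD):
    """Station RMSE plus its validity class."""
    value = rmse(observed_doys, predicted_doys)
    return value, classify_validity(value, threshold)


def cross_source_regression(
    onsets_a: pd.DataFrame,
    onsets_b: pd.DataFrame,
    species: str = "",
    year: int = 0,
) -> CrossSourceFit:
    """OLS of source-a onset on source-b onset over shared stations.

    Each input frame needs columns station_id and doy (or doy_hat). At
    least three shared stations are required.
    """

    def _col(df):
        return "doy_hat" if "doy_hat" in df.columns else "doy"

    merged = onsets_a[["station_id", _col(onsets_a)]].merge(
        onsets_b[["station_id", _col(onsets_b)]], on="station_id", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 shared stations for a regression")
    x = merged.iloc[:, 2].to_numpy(dtype=float)  # source b
    y = merged.iloc[:, 1].to_numpy(dtype=float)  # source a
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: no variance in predictor")
    fit = stats.linregress(x, y)
    return CrossSourceFit(
        species=species,
        year=year,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_shared_stations=len(merged),
    )


def observation_density(
    records: pd.DataFrame,
    year: int | None = None,
    bandwidth_days: float = 5.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gaussian kernel density of observation dates over the year.

    Returns a frame (doy, density) on DOY 1..365 (or ``grid``) whose
    density integrates to ~1 over the real line; ``bandwidth_days`` is
    the kernel standard deviation in days.
    """
    doys = records["doy"]
    if year is not None:
        doys = records.loc[records["year"] == year, "doy"]
    doys = doys.to_numpy(dtype=float)
    if doys.size == 0:
        raise ValueError("no records to build a density from")
    if grid is None:
        grid = np.arange(1, 366, dtype=float)
    if np.ptp(doys) == 0:
        # KDE of a point mass: analytic Gaussian bump
        dens = stats.norm.pdf(grid, loc=doys[0], scale=bandwidth_days)
    else:
        kde = stats.gaussian_kde(doys, bw_method=bandwidth_days / doys.std(ddof=1))
        dens = kde(grid)
    return pd.DataFrame({"doy": grid, "density": dens})
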