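"""Onset-of-flowering estimation: Weibull percentiles with bootstrap bias
correction, and empirical calibration of the species-specific percentile.

The onset of a virtual station is a low quantile of its members'
observation-date distribution. Following the parametric-bootstrap
approach for phenological metrics, a two-parameter Weibull is fitted to
the member DOYs by maximum likelihood; the naive estimate is the fitted
q-quantile, and the reflection correction

    corrected = 2 * naive - mean(bootstrap quantile estimates)

removes the leading bias, where each bootstrap estimate refits the
Weibull to a same-size sample drawn from the fitted distribution.

Because the fitted and bootstrap parameters do not depend on q, they are
computed once per station (:class:`WeibullBootstrapFit`) and evaluated
at any number of candidate percentiles, which is what makes scanning a
dense calibration grid cheap.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stations import VirtualStation

__all__ = [
    "OnsetEstimate",
    "PercentileCalibration",
    "WeibullBootstrapFit",
    "fit_weibull_mle",
    "weibull_percentile",
    "estimate_station_onsets",
    "calibrate_percentile",
]

logger = logging.getLogger(__name__)

MIN_POINTS = 10


def fit_weibull_mle(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-parameter Weibull maximum-likelihood fit, vectorized over rows.

    Parameters
    ----------
    samples
        ``(n,)`` or ``(m, n)`` array of positive values; each row is fitted
        independently.

    Returns
    -------
    shape, scale
        ``(m,)`` arrays (``m = 1`` for 1-D input).

    Notes
    -----
    The profile-likelihood equation for the shape k,

        sum(x^k ln x) / sum(x^k) - 1/k - mean(ln x) = 0,

    is solved by Newton iteration (it is monotone in k); the scale then
    follows in closed form as ``(mean(x^k))^(1/k)``. Values are scaled by
    the row maximum first so ``x^k`` cannot overflow for large shapes.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if np.any(X <= 0):
        raise ValueError("Weibull fit requires strictly positive values")
    xmax = X.max(axis=1, keepdims=True)
    lx = np.log(X / xmax)
    mlx = lx.mean(axis=1)
    sd = lx.std(axis=1)
    k = np.where(sd > 1e-12, 1.2825498301618641 / np.maximum(sd, 1e-12), 1e6)
    for _ in range(100):
        xk = np.exp(k[:, None] * lx)
        A = xk.sum(axis=1)
        B = (xk * lx).sum(axis=1)
        C = (xk * lx * lx).sum(axis=1)
        g = B / A - 1.0 / k - mlx
        gp = (C * A - B * B) / (A * A) + 1.0 / k**2
        step = g / gp
        k_new = k - step
        k = np.where(k_new > 0, k_new, k / 2)
        if np.max(np.abs(step)) < 1e-9 * np.max(k):
            break
    scale = (np.exp(k[:, None] * lx).sum(axis=1) / X.shape[1]) ** (1.0 / k) * xmax[:, 0]
    return k, scale


def _weibull_ppf(q: float, shape: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return scale * (-np.log1p(-q)) ** (1.0 / shape)


@dataclass(frozen=True)
class OnsetEstimate:
    """Bias-corrected onset DOY for one station at percentile q."""

    station_id: str
    q: float
    doy_hat: float
    n: int
    naive_doy: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class WeibullBootstrapFit:
    """Fitted + bootstrap Weibull parameters for one sample of DOYs.

    Encapsulates everything q-independent about the estimator so that
    :meth:`estimate` is a closed-form evaluation per percentile.
    """

    n: int
    shape: float
    scale: float
    boot_shapes: np.ndarray
    boot_scales: np.ndarray
    degenerate_value: float | None = None

    @classmethod
    def from_sample(
        cls, doys: np.ndarray, n_boot: int = 250, seed: int | np.random.SeedSequence = 0
    ) -> "WeibullBootstrapFit":
        doys = np.asarray(doys, dtype=float)
        if len(doys) < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} observations, got {len(doys)}")
        if np.ptp(doys) == 0:
            return cls(
                n=len(doys),
                shape=np.nan,
                scale=np.nan,
                boot_shapes=np.empty(0),
                boot_scales=np.empty(0),
                degenerate_value=float(doys[0]),
            )
        shape, scale = fit_weibull_mle(doys)
        shape_f, scale_f = float(shape[0]), float(scale[0])
        rng = np.random.default_rng(seed)
        boot = scale_f * rng.weibull(shape_f, size=(n_boot, len(doys)))
        # guard against pathological zero draws (probability ~0)
        boot = np.maximum(boot, 1e-12)
        b_shape, b_scale = fit_weibull_mle(boot)
        return cls(
            n=len(doys),
            shape=shape_f,
            scale=scale_f,
            boot_shapes=b_shape,
            boot_scales=b_scale,
        )

    def estimate(self, q: float, station_id: str = "", ci_level: float | None = None) -> OnsetEstimate:
        """Bias-corrected q-quantile (reflection form 2*naive - mean(boot))."""
        if not 0.0 < q < 1.0:
            raise ValueError("percentile q must lie strictly in (0, 1)")
        if self.degenerate_value is not None:
            v = self.degenerate_value
            return OnsetEstimate(station_id=station_id, q=q, doy_hat=v, n=self.n, naive_doy=v)
        naive = float(_weibull_ppf(q, np.array([self.shape]), np.array([self.scale]))[0])
        boots = _weibull_ppf(q, self.boot_shapes, self.boot_scales)
        corrected = 2.0 * naive - float(boots.mean())
        ci_low = ci_high = None
        if ci_level is not None and len(boots):
            alpha = (1.0 - ci_level) / 2.0
            lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
            # reflect the bootstrap interval around the corrected point
            ci_low, ci_high = 2.0 * naive - float(hi), 2.0 * naive - float(lo)
        return OnsetEstimate(
            station_id=station_id,
            q=q,
            doy_hat=corrected,
            n=self.n,
            naive_doy=naive,
            ci_low=ci_low,
            ci_high=ci_high,
        )


def weibull_percentile(
    doys,
    q: float,
    n_boot: int = 250,
    seed: int | np.random.SeedSequence = 0,
    ci_level: float | None = None,
) -> OnsetEstimate:
    """Estimate the q-quantile of a DOY sample via the bias-corrected
    parametric Weibull bootstrap.

    Requires at least 10 observations; a sample of identical values is
    returned as-is without fitting. Deterministic for a fixed seed.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("percentile q must lie strictly in (0, 1)")
    fit = WeibullBootstrapFit.from_sample(np.asarray(doys), n_boot=n_boot, seed=seed)
    return fit.estimate(q, ci_level=ci_level)


def _station_seed(master_seed: int, station_id: str) -> np.random.SeedSequence:
    """Deterministic per-station seed from the master seed and station id."""
    return np.random.SeedSequence([master_seed, zlib.crc32(station_id.encode())])


def fit_network(
    network: list[VirtualStation], n_boot: int = 250, seed: int = 0
) -> dict[str, WeibullBootstrapFit]:
    """Fit the q-independent Weibull bootstrap once per station."""
    fits: dict[str, WeibullBootstrapFit] = {}
    for st in network:
        try:
            fits[st.station_id] = WeibullBootstrapFit.from_sample(
                st.member_doys, n_boot=n_boot, seed=_station_seed(seed, st.station_id)
            )
        except ValueError as exc:
            logger.warning("station %s skipped: %s", st.station_id, exc)
    return fits


def estimate_station_onsets(
    network: list[VirtualStation],
    q: float,
    n_boot: int = 250,
    seed: int = 0,
    fits: dict[str, WeibullBootstrapFit] | None = None,
) -> list[OnsetEstimate]:
    """One bias-corrected onset estimate per virtual station.

    Per-station random streams are derived from ``seed`` and the station
    id, so estimates do not depend on network order. A precomputed
    ``fits`` mapping (from :func:`fit_network`) may be passed to reuse
    bootstrap work across percentiles.
    """
    if fits is None:
        fits = fit_network(network, n_boot=n_boot, seed=seed)
    return [
        fits[st.station_id].estimate(q, station_id=st.station_id)
        for st in network
        if st.station_id in fits
    ]


def estimates_frame(estimates: list[OnsetEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station_id": [e.station_id for e in estimates],
            "q": [e.q for e in estimates],
            "doy_hat": [e.doy_hat for e in estimates],
            "n": [e.n for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )


@dataclass(frozen=True)
class PercentileCalibration:
    """Result of matching the opportunistic map median to a reference map."""

    species: str
    q_star: float
    candidate_grid: tuple[float, ...]
    reference_median: float
    achieved_median: float
    medians: dict[float, float] = field(default_factory=dict)


def calibrate_percentile(
    network: list[VirtualStation],
    reference_median: float,
    interpolate_fn,
    candidate_grid=None,
    n_boot: int = 250,
    seed: int = 0,
    species: str = "",
) -> PercentileCalibration:
    """Choose the percentile whose interpolated map median best matches
    the reference map median.

    For every candidate q the full chain (station onsets -> circle
    regressions -> IDW map) is run via ``interpolate_fn(estimates) ->
    PhenoMap`` and the median over unmasked cells compared with
    ``reference_median``; ties break toward the smaller q. Candidates
    whose interpolation fails are skipped with a logged reason.
    """
    if candidate_grid is None:
        candidate_grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    candidate_grid = tuple(float(q) for q in candidate_grid)
    if not candidate_grid:
        raise ValueError("candidate_grid must be non-empty")

    fits = fit_network(network, n_boot=n_boot, seed=seed)
    medians: dict[float, float] = {}
    for q in candidate_grid:
        try:
            estimates = estimate_station_onsets(network, q, fits=fits)
            pheno = interpolate_fn(estimates)
            medians[q] = float(np.median(pheno.unmasked_values))
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            logger.warning("calibration candidate q=%.3f failed: %s", q, exc)
    if not medians:
        raise RuntimeError("all calibration candidates failed")
    # ties toward the smaller q: iterate in ascending order, strict improvement
    q_star, best = None, np.inf
    for q in sorted(medians):
        err = abs(medians[q] - reference_median)
        if err < best - 1e-12:
            q_star, best = q, err
    return PercentileCalibration(
        species=species,
        q_star=float(q_star),
        candidate_grid=candidate_grid,
        reference_median=float(reference_median),
        achieved_median=medians[q_star],
        medians=medians,
    )
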