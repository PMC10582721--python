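"""Virtual-station construction: match opportunistic records to anchors.

A reference (anchor) station contributes a "virtual station" when at
least ``min_records`` records of the species/year lie within an
expanding great-circle radius (5 km, growing in 1 km steps to at most
55 km) AND within +-25 m of the anchor's elevation. The smallest radius
reaching the quorum wins; records may belong to several stations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StationParams",
    "VirtualStation",
    "haversine_m",
    "assign_virtual_station",
    "build_network",
    "network_frames",
    "network_from_frames",
]

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between WGS84 points (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class StationParams:
    """Radius schedule and filters for virtual-station assignment."""

    initial_radius_m: float = 5000.0
    radius_step_m: float = 1000.0
    max_radius_m: float = 55000.0
    min_records: int = 35
    elev_band_m: float = 25.0

    def __post_init__(self) -> None:
        if self.initial_radius_m > self.max_radius_m:
            raise ValueError("initial_radius_m must not exceed max_radius_m")
        if min(self.initial_radius_m, self.radius_step_m, self.max_radius_m, self.elev_band_m) <= 0:
            raise ValueError("radii, step and elevation band must be positive")
        if self.min_records < 1:
            raise ValueError("min_records must be >= 1")

    def radii(self) -> np.ndarray:
        """The tried radii: initial, initial+step, ... up to max (inclusive)."""
        n = int(np.floor((self.max_radius_m - self.initial_radius_m) / self.radius_step_m + 1e-9))
        return self.initial_radius_m + self.radius_step_m * np.arange(n + 1)


@dataclass
class VirtualStation:
    """A quorum of records matched to one anchor."""

    station_id: str
    lat: float
    lon: float
    elev_m: float
    species: str
    year: int
    final_radius_m: float
    member_record_ids: np.ndarray
    member_doys: np.ndarray
    anchor_onset_doy: float | None = None

    @property
    def n_records(self) -> int:
        return len(self.member_record_ids)


def assign_virtual_station(
    records: pd.DataFrame, anchor: pd.Series, params: StationParams = StationParams()
) -> VirtualStation | None:
    """Build the virtual station for one anchor, or return None.

    ``records`` must already be restricted to one species and year and
    carry columns record_id, lat, lon, elev_m, doy. Membership at radius
    r is distance <= r (great circle) and |elev - anchor elev| <= band,
    both inclusive; the smallest radius in the schedule reaching
    ``min_records`` members is kept.
    """
    if not np.isfinite(anchor["elev_m"]):
        raise ValueError(f"anchor {anchor['station_id']} has no elevation; band filter undefined")
    if len(records) == 0:
        return None
    dist = haversine_m(records["lat"].to_numpy(), records["lon"].to_numpy(), anchor["lat"], anchor["lon"])
    in_band = np.abs(records["elev_m"].to_numpy() - anchor["elev_m"]) <= params.elev_band_m
    qualifying = dist[in_band]
    if len(qualifying) < params.min_records:
        return None
    # smallest scheduled radius reaching the quorum = schedule ceiling of the
    # min_records-th smallest qualifying distance
    d_quorum = np.partition(qualifying, params.min_records - 1)[params.min_records - 1]
    if d_quorum > params.max_radius_m:
        return None
    steps = max(0.0, np.ceil((d_quorum - params.initial_radius_m) / params.radius_step_m))
    radius = params.initial_radius_m + params.radius_step_m * steps
    if radius > params.max_radius_m + 1e-9:
        return None
    members = in_band & (dist <= radius)
    return VirtualStation(
        station_id=str(anchor["station_id"]),
        lat=float(anchor["lat"]),
        lon=float(anchor["lon"]),
        elev_m=float(anchor["elev_m"]),
        species=str(anchor.get("species", records["species"].iloc[0] if "species" in records else "")),
        year=int(anchor.get("year", records["year"].iloc[0] if "year" in records else 0)),
        final_radius_m=float(radius),
        member_record_ids=records.loc[members, "record_id"].to_numpy(),
        member_doys=records.loc[members, "doy"].to_numpy(dtype=float),
        anchor_onset_doy=float(anchor["onset_doy"])
        if "onset_doy" in anchor and pd.notna(anchor["onset_doy"])
        else None,
    )


def build_network(
    records: pd.DataFrame,
    anchors: pd.DataFrame,
    params: StationParams = StationParams(),
) -> list[VirtualStation]:
    """Assign a virtual station to every anchor that reaches the quorum.

    Output order follows anchor order; anchors that never reach the
    quorum are dropped. Records are shared between overlapping stations.
    """
    out = []
    for _, anchor in anchors.iterrows():
        st = assign_virtual_station(records, anchor, params)
        if st is not None:
            out.append(st)
    return out


def network_frames(network: list[VirtualStation]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries: per-station frame and station-member long frame."""
    stations = pd.DataFrame(
        {
            "station_id": [s.station_id for s in network],
            "lat": [s.lat for s in network],
            "lon": [s.lon for s in network],
            "elev_m": [s.elev_m for s in network],
            "species": [s.species for s in network],
            "year": [s.year for s in network],
            "final_radius_m": [s.final_radius_m for s in network],
            "n_records": [s.n_records for s in network],
        }
    )
    members = pd.DataFrame(
        {
            "station_id": np.repeat([s.station_id for s in network], [s.n_records for s in network]),
            "record_id": np.concatenate([s.member_record_ids for s in network])
            if network
            else np.array([], dtype=object),
        }
    )
    return stations, members


def network_from_frames(
    stations: pd.DataFrame, members: pd.DataFrame, records: pd.DataFrame
) -> list[VirtualStation]:
    """Rebuild VirtualStation objects from the CSV-round-tripped frames."""
    recs = records.set_index("record_id")
    grouped = members.groupby("station_id")["record_id"]
    out = []
    for _, st in stations.iterrows():
        ids = grouped.get_group(st["station_id"])
        out.append(
            VirtualStation(
                station_id=str(st["station_id"]),
                lat=float(st["lat"]),
                lon=float(st["lon"]),
                elev_m=float(st["elev_m"]),
                species=str(st.get("species", "")),
                year=int(st.get("year", 0)),
                final_radius_m=float(st["final_radius_m"]),
                member_record_ids=ids.to_numpy(),
                member_doys=recs.loc[ids, "doy"].to_numpy(dtype=float),
            )
        )
    return out
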