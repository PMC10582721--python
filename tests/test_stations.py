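"""Virtual-station assignment, checked against an exhaustive radius scan."""

import numpy as np
import pandas as pd
import pytest

from phenomap import StationParams, assign_virtual_station, build_network, haversine_m
from phenomap.stations import EARTH_RADIUS_M

from conftest import make_anchor, make_records


def offset_latlon(lat, lon, north_m, east_m):
    """Move a point by metric offsets (small-displacement approximation)."""
    dlat = np.degrees(north_m / EARTH_RADIUS_M)
    dlon = np.degrees(east_m / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    return lat + dlat, lon + dlon


def records_at_distance(anchor, dist_m, n, elev=None, bearing_deg=None, start=0):
    elev = anchor["elev_m"] if elev is None else elev
    bearings = np.linspace(0, 2 * np.pi, n, endpoint=False) if bearing_deg is None else np.radians(
        np.full(n, bearing_deg)
    )
    lats, lons = [], []
    for b in bearings:
        lat, lon = offset_latlon(anchor["lat"], anchor["lon"], dist_m * np.cos(b), dist_m * np.sin(b))
        lats.append(lat)
        lons.append(lon)
    return make_records(lats, lons, np.full(n, elev), np.full(n, 150), start=start)


def brute_force_assign(records, anchor, params):
    """Independent oracle: literal scan over the radius schedule.

    Distances via the spherical law of cosines (a different formula from
    the implementation's haversine).
    """
    lat1, lon1 = np.radians(anchor["lat"]), np.radians(anchor["lon"])
    lat2, lon2 = np.radians(records["lat"].to_numpy()), np.radians(records["lon"].to_numpy())
    cosc = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(lon2 - lon1)
    dist = EARTH_RADIUS_M * np.arccos(np.clip(cosc, -1, 1))
    in_band = np.abs(records["elev_m"].to_numpy() - anchor["elev_m"]) <= params.elev_band_m
    r = params.initial_radius_m
    while r <= params.max_radius_m + 1e-9:
        members = in_band & (dist <= r)
        if members.sum() >= params.min_records:
            return r, set(records.loc[members, "record_id"])
        r += params.radius_step_m
    return None


class TestAssignExamples:
    def test_quorum_inside_initial_radius(self):
        anchor = make_anchor()
        recs = records_at_distance(anchor, 3000, 40)
        st = assign_virtual_station(recs, anchor)
        assert st is not None
        assert st.final_radius_m == 5000
        assert st.n_records == 40

    def test_no_records_yields_none(self):
        assert assign_virtual_station(make_records([], [], [], []), make_anchor()) is None

    def test_split_clusters_need_expanded_radius(self):
        anchor = make_anchor()
        recs = pd.concat(
            [records_at_distance(anchor, 4000, 20), records_at_distance(anchor, 29500, 20, start=20)],
            ignore_index=True,
        )
        st = assign_virtual_station(recs, anchor)
        assert st.final_radius_m == 30000
        assert st.n_records == 40

    def test_34_records_never_reach_quorum(self):
        anchor = make_anchor()
        recs = records_at_distance(anchor, 10000, 34)
        assert assign_virtual_station(recs, anchor) is None

    def test_elevation_band_is_inclusive_at_25m(self):
        anchor = make_anchor(elev_m=300.0)
        at_band = records_at_distance(anchor, 2000, 35, elev=325.0)
        beyond = records_at_distance(anchor, 2000, 35, elev=325.5)
        assert assign_virtual_station(at_band, anchor).n_records == 35
        assert assign_virtual_station(beyond, anchor) is None

    def test_anchor_without_elevation_raises(self):
        anchor = make_anchor(elev_m=np.nan)
        recs = records_at_distance(make_anchor(), 2000, 40)
        with pytest.raises(ValueError, match="elevation"):
            assign_virtual_station(recs, anchor)

    def test_members_beyond_55km_cannot_form_station(self):
        anchor = make_anchor()
        recs = records_at_distance(anchor, 56000, 100)
        assert assign_virtual_station(recs, anchor) is None


class TestBuildNetwork:
    def test_nearby_anchors_share_records(self):
        a1 = make_anchor(station_id="A1")
        lat2, lon2 = offset_latlon(a1["lat"], a1["lon"], 1000, 0)
        a2 = make_anchor(lat=lat2, lon=lon2, station_id="A2")
        recs = records_at_distance(a1, 2000, 50)
        net = build_network(recs, pd.DataFrame([a1, a2]))
        assert [s.station_id for s in net] == ["A1", "A2"]
        assert set(net[0].member_record_ids) == set(net[1].member_record_ids) == set(recs.record_id)

    def test_distant_clusters_stay_disjoint(self):
        a1 = make_anchor(station_id="A1")
        a2 = make_anchor(lat=49.0, lon=8.0, station_id="A2")  # ~111 km away
        recs = pd.concat(
            [records_at_distance(a1, 3000, 40), records_at_distance(a2, 3000, 40, start=40)],
            ignore_index=True,
        )
        net = build_network(recs, pd.DataFrame([a1, a2]))
        assert len(net) == 2
        assert not (set(net[0].member_record_ids) & set(net[1].member_record_ids))


def random_scenarios(n_scenarios, seed, n_records_range=(0, 70)):
    rng = np.random.default_rng(seed)
    for i in range(n_scenarios):
        n = int(rng.integers(*n_records_range))
        anchor = make_anchor(
            lat=float(rng.uniform(47, 55)), lon=float(rng.uniform(6, 15)),
            elev_m=float(rng.uniform(0, 800)), station_id=f"A{i}",
        )
        # cluster records around the anchor at assorted scales so all radii
        # and both filters are exercised
        d = rng.exponential(20_000, n)
        b = rng.uniform(0, 2 * np.pi, n)
        lats, lons = offset_latlon(anchor["lat"], anchor["lon"], d * np.cos(b), d * np.sin(b))
        elevs = anchor["elev_m"] + rng.normal(0, 30, n)
        recs = make_records(lats, lons, elevs, rng.integers(50, 250, n if n else 0))
        params = StationParams(
            initial_radius_m=float(rng.choice([3000, 5000, 8000])),
            radius_step_m=float(rng.choice([500, 1000, 2000])),
            max_radius_m=float(rng.choice([30000, 55000])),
            min_records=int(rng.integers(1, 40)),
            elev_band_m=float(rng.choice([10.0, 25.0, 50.0])),
        )
        yield recs, anchor, params


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_scenarios(self):
        """Membership, minimal radius and the none-result must agree with a
        literal scan over the radius schedule on randomized inputs."""
        for recs, anchor, params in random_scenarios(300, seed=101):
            got = assign_virtual_station(recs, anchor, params)
            want = brute_force_assign(recs, anchor, params)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got.final_radius_m == pytest.approx(want[0])
                assert set(got.member_record_ids) == want[1]

    def test_count_monotone_in_radius_and_returned_radius_minimal(self):
        for recs, anchor, params in random_scenarios(40, seed=7):
            st = assign_virtual_station(recs, anchor, params)
            if st is None:
                continue
            dist = haversine_m(recs.lat.to_numpy(), recs.lon.to_numpy(), anchor["lat"], anchor["lon"])
            in_band = np.abs(recs.elev_m.to_numpy() - anchor["elev_m"]) <= params.elev_band_m
            counts = [(in_band & (dist <= r)).sum() for r in params.radii()]
            assert all(a <= b for a, b in zip(counts, counts[1:]))
            smaller = [r for r in params.radii() if r < st.final_radius_m]
            assert all(
                (in_band & (dist <= r)).sum() < params.min_records for r in smaller
            )

    def test_far_away_record_changes_nothing(self):
        anchor = make_anchor()
        recs = records_at_distance(anchor, 8000, 40)
        far = make_records([54.9], [14.9], [anchor["elev_m"]], [150], start=999)
        st1 = assign_virtual_station(recs, anchor)
        st2 = assign_virtual_station(pd.concat([recs, far], ignore_index=True), anchor)
        assert st1.final_radius_m == st2.final_radius_m
        assert set(st1.member_record_ids) == set(st2.member_record_ids)

    def test_raising_min_records_only_removes_stations(self, small_world):
        recs = small_world.records[small_world.records.year == 2020]
        anchors = small_world.anchors[small_world.anchors.year == 2020]
        ids_lo = {s.station_id for s in build_network(recs, anchors, StationParams(min_records=20))}
        ids_hi = {s.station_id for s in build_network(recs, anchors, StationParams(min_records=40))}
        assert ids_hi <= ids_lo
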