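import datetime as dt
import math
import random

import pytest

from vitidss.types import DailyWeather, StationMeta, StationNetwork, SubDailyObservation
from vitidss.weather_core import (
    EARTH_RADIUS_KM,
    aggregate_daily,
    fill_gaps,
    haversine_km,
    nearest_station,
    parse_observations,
    qc_validate,
    read_daily_csv,
    write_daily_csv,
)


def subdaily_day(day=dt.date(2021, 6, 1), temps=None, precip=0.5, station="ws1", n=48):
    base = dt.datetime.combine(day, dt.time())
    temps = temps if temps is not None else [15.0] * n
    return [
        SubDailyObservation(
            station_id=station,
            timestamp=base + dt.timedelta(minutes=30 * i),
            temp=temps[i % len(temps)],
            rh=70.0,
            precip=precip,
        )
        for i in range(n)
    ]


class TestParse:
    def test_csv_with_out_of_range_row_is_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(
            "station_id,timestamp,temp_c,rh_pct,precip_mm\n"
            "ws1,2021-06-01T00:00:00,15.0,70,0.0\n"
            "ws1,2021-06-01T00:30:00,15.5,120,0.0\n"
            "ws1,2021-06-01T01:00:00,16.0,71,0.2\n"
        )
        result = parse_observations(p)
        assert len(result.records) == 2
        assert len(result.report) == 1

    def test_empty_file_yields_empty_collection_with_warning(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        result = parse_observations(p)
        assert result.records == []
        assert result.report.warnings

    def test_missing_required_column_is_a_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("station_id,rh_pct\nws1,70\n")
        with pytest.raises(ValueError, match="required column"):
            parse_observations(p)

    def test_json_day_parses_48_records_on_30min_cadence(self, tmp_path):
        import json

        rows = [
            {
                "station_id": "ws1",
                "timestamp": (
                    dt.datetime(2021, 6, 1) + dt.timedelta(minutes=30 * i)
                ).isoformat(),
                "temp_c": 15.0,
                "precip_mm": 0.1,
            }
            for i in range(48)
        ]
        p = tmp_path / "obs.json"
        p.write_text(json.dumps(rows))
        result = parse_observations(p, format="json")
        assert len(result.records) == 48
        deltas = {
            (b.timestamp - a.timestamp).total_seconds()
            for a, b in zip(result.records, result.records[1:])
        }
        assert deltas == {1800.0}

    def test_unparseable_timestamp_collected_as_row_error(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(
            "station_id,timestamp,temp_c\nws1,not-a-time,15.0\nws1,2021-06-01T00:00:00,15.0\n"
        )
        result = parse_observations(p)
        assert len(result.records) == 1
        assert result.report.violations[0].rule == "parse"


class TestAggregate:
    def test_alternating_temps_and_constant_precip(self):
        obs = subdaily_day(temps=[10.0, 20.0], precip=0.5)
        agg = aggregate_daily(obs, "site")
        (day,) = agg.days
        assert (day.tmin, day.tmax, day.tmean) == (10.0, 20.0, 15.0)
        assert day.precip == pytest.approx(24.0)

    def test_constant_series_collapses_to_single_value(self):
        obs = subdaily_day(temps=[10.0])
        (day,) = aggregate_daily(obs, "site").days
        assert day.tmin == day.tmax == day.tmean == 10.0

    def test_dropout_day_flagged_incomplete_below_threshold(self):
        obs = subdaily_day(n=10)
        agg = aggregate_daily(obs, "site", completeness=0.8)
        assert agg.days == []
        assert agg.incomplete == {dt.date(2021, 6, 1): 10}

    def test_permutation_invariance(self):
        obs = subdaily_day(temps=[8.0, 12.0, 17.0, 21.0], precip=0.3)
        shuffled = obs[:]
        random.Random(0).shuffle(shuffled)
        assert aggregate_daily(obs, "s").days == aggregate_daily(shuffled, "s").days

    def test_fuzzed_streams_respect_temperature_ordering(self):
        rnd = random.Random(42)
        for _ in range(50):
            temps = [rnd.uniform(-20, 45) for _ in range(48)]
            (day,) = aggregate_daily(subdaily_day(temps=temps), "s").days
            assert day.tmin <= day.tmean <= day.tmax


class TestNearestStation:
    def network(self, *stations):
        return StationNetwork(stations=list(stations))

    def test_query_at_station_coordinates_returns_it_at_zero_distance(self):
        st = StationMeta("a", 42.0, 19.0, kind="national")
        meta, d = nearest_station(42.0, 19.0, self.network(st))
        assert meta.station_id == "a"
        assert d == 0.0

    def test_two_station_tiebreak_by_distance(self):
        a = StationMeta("a", 0.0, 0.0, kind="national")
        b = StationMeta("b", 0.0, 1.0, kind="national")
        meta, d = nearest_station(0.0, 0.4, self.network(a, b))
        assert meta.station_id == "a"
        assert d == pytest.approx(44.5, abs=0.2)

    def test_all_offline_with_require_online_errors(self):
        st = StationMeta("a", 42.0, 19.0, status="offline")
        with pytest.raises(LookupError, match="no station"):
            nearest_station(42.0, 19.0, self.network(st), require_online=True)

    def test_haversine_symmetry_and_identity(self):
        rnd = random.Random(1)
        for _ in range(20):
            lat1, lon1 = rnd.uniform(-80, 80), rnd.uniform(-180, 180)
            lat2, lon2 = rnd.uniform(-80, 80), rnd.uniform(-180, 180)
            assert haversine_km(lat1, lon1, lat1, lon1) == 0.0
            assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(
                haversine_km(lat2, lon2, lat1, lon1)
            )

    def test_haversine_matches_spherical_law_of_cosines(self):
        # independent oracle: spherical law of cosines on the same sphere
        rnd = random.Random(2)
        for _ in range(100):
            lat1, lon1 = rnd.uniform(-80, 80), rnd.uniform(-180, 180)
            lat2, lon2 = rnd.uniform(-80, 80), rnd.uniform(-180, 180)
            p1, p2 = math.radians(lat1), math.radians(lat2)
            cosc = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(
                math.radians(lon2 - lon1)
            )
            oracle = EARTH_RADIUS_KM * math.acos(max(-1.0, min(1.0, cosc)))
            got = haversine_km(lat1, lon1, lat2, lon2)
            assert got == pytest.approx(oracle, rel=0.005, abs=1e-6)


def daily(day, site="vine", **kw):
    defaults = dict(tmin=10.0, tmax=20.0, tmean=15.0, precip=1.0, rh_mean=70.0)
    defaults.update(kw)
    return DailyWeather(site_id=site, date=day, **defaults)


class TestFillGaps:
    def setup_method(self):
        self.site = StationMeta("vine", 42.4, 19.2, kind="iot")
        self.donor = StationMeta("zhms1", 42.5, 19.3, kind="national")

    def test_gapless_series_unchanged(self):
        series = [daily(dt.date(2021, 6, 1) + dt.timedelta(days=i)) for i in range(5)]
        net = StationNetwork(stations=[self.site, self.donor])
        result = fill_gaps(series, self.site, net)
        assert result.series == series
        assert result.unfilled == []

    def test_missing_day_filled_from_national_donor_with_provenance(self):
        series = [
            daily(dt.date(2021, 6, 1)),
            daily(dt.date(2021, 6, 3)),
        ]
        donor_day = daily(dt.date(2021, 6, 2), site="zhms1", tmean=17.0, tmax=22.0)
        net = StationNetwork(
            stations=[self.site, self.donor], daily={"zhms1": [donor_day]}
        )
        result = fill_gaps(series, self.site, net)
        filled = [d for d in result.series if d.source == "gap_filled"]
        assert len(filled) == 1
        assert filled[0].fill_station == "zhms1"
        assert filled[0].fill_distance_km == pytest.approx(
            haversine_km(42.4, 19.2, 42.5, 19.3)
        )
        assert filled[0].tmean == 17.0

    def test_unfillable_day_stays_missing_and_is_counted(self):
        series = [daily(dt.date(2021, 6, 1)), daily(dt.date(2021, 6, 3))]
        net = StationNetwork(stations=[self.site, self.donor])
        result = fill_gaps(series, self.site, net)
        assert result.unfilled == [dt.date(2021, 6, 2)]
        assert len(result.series) == 2

    def test_idempotence(self):
        series = [daily(dt.date(2021, 6, 1)), daily(dt.date(2021, 6, 4))]
        donor_days = [
            daily(dt.date(2021, 6, 2), site="zhms1"),
            daily(dt.date(2021, 6, 3), site="zhms1"),
        ]
        net = StationNetwork(stations=[self.site, self.donor], daily={"zhms1": donor_days})
        once = fill_gaps(series, self.site, net)
        twice = fill_gaps(once.series, self.site, net)
        assert twice.series == once.series


class TestQC:
    def test_duplicate_timestamp_flagged(self):
        obs = subdaily_day(n=2)
        report = qc_validate(obs + [obs[0]])
        assert any(v.rule == "duplicate" for v in report.violations)

    def test_out_of_range_temperature_flagged(self):
        base = dt.datetime(2021, 6, 1)
        obs = [SubDailyObservation("ws1", base, temp=-80.0)]
        report = qc_validate(obs, limits={"temp": (-30.0, 50.0)})
        assert len(report) == 1
        assert report.violations[0].rule == "range"

    def test_clean_stream_passes(self):
        assert qc_validate(subdaily_day()).ok


def test_daily_csv_round_trip(tmp_path):
    series = [
        daily(dt.date(2021, 6, 1)),
        DailyWeather(
            site_id="vine",
            date=dt.date(2021, 6, 2),
            tmin=9.0,
            tmax=19.0,
            tmean=14.0,
            precip=0.0,
            rh_mean=None,
            source="gap_filled",
            fill_station="zhms1",
            fill_distance_km=13.9,
        ),
    ]
    path = tmp_path / "daily.csv"
    write_daily_csv(series, path)
    assert read_daily_csv(path) == series
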