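"""Ingestion, QC, daily aggregation and gap-filling of station observations.

The pipeline is: parse sub-daily sensor records (30-min cadence, 48/day),
validate them against plausibility limits, aggregate to UTC calendar days,
and fill missing or incomplete days from the nearest national weather
station, recording donor identity and distance as provenance.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import DailyWeather, StationMeta, StationNetwork, SubDailyObservation

EARTH_RADIUS_KM = 6371.0088

#: expected sub-daily samples per day at the nominal 30-min cadence
SAMPLES_PER_DAY = 48
#: fraction of expected samples a day needs to be aggregated rather than gap
COMPLETENESS_THRESHOLD = 0.8

#: default plausibility limits per variable (inclusive bounds)
DEFAULT_QC_LIMITS: dict[str, tuple[float, float]] = {
    "temp": (-30.0, 50.0),
    "rh": (0.0, 100.0),
    "precip": (0.0, 200.0),
    "wind_speed": (0.0, 75.0),
    "pressure": (850.0, 1100.0),
}


@dataclass(frozen=True)
class QCViolation:
    station_id: str
    timestamp: Optional[dt.datetime]
    rule: str
    detail: str


@dataclass
class QCReport:
    violations: list[QCViolation] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.violations)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class IngestResult:
    """Parsed observations plus a row-level error report."""

    records: list[SubDailyObservation]
    report: QCReport


@dataclass
class DailyAggregation:
    """Complete aggregated days plus the days rejected as incomplete."""

    days: list[DailyWeather]
    incomplete: dict[dt.date, int] = field(default_factory=dict)


@dataclass
class FillResult:
    series: list[DailyWeather]
    unfilled: list[dt.date] = field(default_factory=list)


_COLUMN_MAP = {
    "temp_c": "temp",
    "rh_pct": "rh",
    "precip_mm": "precip",
    "wind_ms": "wind_speed",
    "pressure_hpa": "pressure",
    "co2_ppm": "co2",
    "uv_uw_cm2": "uv",
}
_REQUIRED = ("station_id", "timestamp", "temp_c")


def _parse_timestamp(raw: str) -> dt.datetime:
    ts = dt.datetime.fromisoformat(str(raw).replace("Z", "+00:00"))
    if ts.tzinfo is not None:
        ts = ts.astimezone(dt.timezone.utc).replace(tzinfo=None)
    return ts


def _row_to_obs(row: dict) -> SubDailyObservation:
    kwargs: dict = {
        "station_id": str(row["station_id"]),
        "timestamp": _parse_timestamp(row["timestamp"]),
        "temp": float(row["temp_c"]),
    }
    for col, attr in _COLUMN_MAP.items():
        if col == "temp_c":
            continue
        val = row.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            continue
        kwargs[attr] = float(val)
    if "precip" not in kwargs:
        kwargs["precip"] = 0.0
    return SubDailyObservation(**kwargs)


def parse_observations(path: str | Path, format: Optional[str] = None) -> IngestResult:
    """Parse sub-daily observations from CSV or JSON.

    Malformed rows (bad timestamps, out-of-range values) are excluded and
    collected in the report; parsing never aborts on a single bad row.

    Raises
    ------
    ValueError
        If a required column (station_id, timestamp, temp_c) is absent.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    report = QCReport()

    if format == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            report.warnings.append(f"{path}: empty file")
            return IngestResult([], report)
        rows = frame.to_dict("records")
    elif format == "json":
        payload = json.loads(path.read_text() or "[]")
        if not payload:
            report.warnings.append(f"{path}: empty file")
            return IngestResult([], report)
        rows = payload
    else:
        raise ValueError(f"unknown format {format!r}")

    if rows:
        missing = [c for c in _REQUIRED if c not in rows[0]]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")

    records: list[SubDailyObservation] = []
    for i, row in enumerate(rows):
        try:
            records.append(_row_to_obs(row))
        except (ValueError, TypeError, KeyError) as exc:
            report.violations.append(
                QCViolation(
                    station_id=str(row.get("station_id", "?")),
                    timestamp=None,
                    rule="parse",
                    detail=f"row {i}: {exc}",
                )
            )
    records.sort(key=lambda o: (o.station_id, o.timestamp))
    return IngestResult(records, report)


def qc_validate(
    obs: Sequence[SubDailyObservation],
    limits: Optional[dict[str, tuple[float, float]]] = None,
) -> QCReport:
    """Check observations against plausibility limits without mutating them.

    Reports out-of-range values, duplicate timestamps and non-monotonic
    timestamps per station.
    """
    limits = dict(DEFAULT_QC_LIMITS if limits is None else limits)
    report = QCReport()
    last_seen: dict[str, dt.datetime] = {}
    seen: set[tuple[str, dt.datetime]] = set()
    for o in obs:
        key = (o.station_id, o.timestamp)
        if key in seen:
            report.violations.append(
                QCViolation(o.station_id, o.timestamp, "duplicate", "duplicate timestamp")
            )
        seen.add(key)
        prev = last_seen.get(o.station_id)
        if prev is not None and o.timestamp < prev:
            report.violations.append(
                QCViolation(o.station_id, o.timestamp, "order", f"timestamp before {prev}")
            )
        last_seen[o.station_id] = max(o.timestamp, prev) if prev else o.timestamp
        for var, (lo, hi) in limits.items():
            val = getattr(o, var, None)
            if val is not None and not (lo <= val <= hi):
                report.violations.append(
                    QCViolation(
                        o.station_id,
                        o.timestamp,
                        "range",
                        f"{var}={val} outside [{lo}, {hi}]",
                    )
                )
    return report


def aggregate_daily(
    obs: Iterable[SubDailyObservation],
    site_id: str,
    completeness: float = COMPLETENESS_THRESHOLD,
    expected_samples: int = SAMPLES_PER_DAY,
    source: str = "iot",
) -> DailyAggregation:
    """Aggregate sub-daily records into daily weather.

    Per UTC calendar day: tmin/tmax/tmean from the temperature samples,
    precipitation summed, relative humidity averaged. Days with fewer than
    ``completeness * expected_samples`` temperature samples are rejected as
    incomplete (they become gaps for :func:`fill_gaps`); days with zero
    samples are simply absent — never fabricated.
    """
    by_day: dict[dt.date, list[SubDailyObservation]] = defaultdict(list)
    for o in obs:
        by_day[o.timestamp.date()].append(o)

    min_samples = completeness * expected_samples
    days: list[DailyWeather] = []
    incomplete: dict[dt.date, int] = {}
    for day in sorted(by_day):
        # deterministic reduction order makes aggregation exactly
        # permutation-invariant despite float summation
        samples = sorted(by_day[day], key=lambda s: (s.timestamp, s.temp, s.precip))
        if len(samples) < min_samples:
            incomplete[day] = len(samples)
            continue
        temps = [s.temp for s in samples]
        rhs = [s.rh for s in samples if s.rh is not None]
        days.append(
            DailyWeather(
                site_id=site_id,
                date=day,
                tmin=min(temps),
                tmax=max(temps),
                tmean=sum(temps) / len(temps),
                precip=sum(s.precip for s in samples),
                rh_mean=sum(rhs) / len(rhs) if rhs else None,
                source=source,
            )
        )
    return DailyAggregation(days=days, incomplete=incomplete)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, Earth radius 6371.0088 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def nearest_station(
    lat: float,
    lon: float,
    network: StationNetwork,
    require_online: bool = False,
    kind: Optional[str] = None,
    exclude: Sequence[str] = (),
) -> tuple[StationMeta, float]:
    """Return the great-circle-nearest eligible station and its distance.

    Equidistant candidates are broken by lexicographic station_id.

    Raises
    ------
    LookupError
        If no station satisfies the eligibility filters.
    """
    candidates = [
        s
        for s in network.stations
        if s.station_id not in exclude
        and (kind is None or s.kind == kind)
        and (not require_online or s.status == "online")
    ]
    if not candidates:
        raise LookupError("no station available")
    best = min(
        candidates,
        key=lambda s: (haversine_km(lat, lon, s.lat, s.lon), s.station_id),
    )
    return best, haversine_km(lat, lon, best.lat, best.lon)


def _missing_dates(series: Sequence[DailyWeather]) -> list[dt.date]:
    present = {d.date for d in series}
    first, last = min(present), max(present)
    out, day = [], first
    while day <= last:
        if day not in present:
            out.append(day)
        day += dt.timedelta(days=1)
    return out


def fill_gaps(
    site_series: Sequence[DailyWeather],
    site_meta: StationMeta,
    network: StationNetwork,
) -> FillResult:
    """Fill missing days from the nearest national station holding that day.

    Substitution is whole-record: the donor's daily values are adopted for
    the site, marked source="gap_filled" with the donor id and distance.
    Days no donor has pass through as missing (listed in ``unfilled``).
    Idempotent: a series without gaps is returned unchanged.
    """
    if not site_series:
        return FillResult(series=[], unfilled=[])
    donors = sorted(
        (s for s in network.stations if s.kind == "national"),
        key=lambda s: (
            haversine_km(site_meta.lat, site_meta.lon, s.lat, s.lon),
            s.station_id,
        ),
    )
    filled: list[DailyWeather] = list(site_series)
    unfilled: list[dt.date] = []
    for day in _missing_dates(site_series):
        for donor in donors:
            rec = network.day(donor.station_id, day)
            if rec is None:
                continue
            filled.append(
                DailyWeather(
                    site_id=site_meta.station_id,
                    date=day,
                    tmin=rec.tmin,
                    tmax=rec.tmax,
                    tmean=rec.tmean,
                    precip=rec.precip,
                    rh_mean=rec.rh_mean,
                    source="gap_filled",
                    fill_station=donor.station_id,
                    fill_distance_km=haversine_km(
                        site_meta.lat, site_meta.lon, donor.lat, donor.lon
                    ),
                )
            )
            break
        else:
            unfilled.append(day)
    filled.sort(key=lambda d: d.date)
    return FillResult(series=filled, unfilled=unfilled)


# ---------------------------------------------------------------------------
# tabular I/O


def daily_to_frame(series: Sequence[DailyWeather]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [d.site_id for d in series],
            "date": [d.date.isoformat() for d in series],
            "tmin_c": [d.tmin for d in series],
            "tmax_c": [d.tmax for d in series],
            "tmean_c": [d.tmean for d in series],
            "precip_mm": [d.precip for d in series],
            "rh_mean_pct": [d.rh_mean for d in series],
            "source": [d.source for d in series],
            "fill_station": [d.fill_station for d in series],
            "fill_distance_km": [d.fill_distance_km for d in series],
        }
    )


def frame_to_daily(frame: pd.DataFrame) -> list[DailyWeather]:
    out = []
    for row in frame.to_dict("records"):
        rh = row.get("rh_mean_pct")
        fill_station = row.get("fill_station")
        fill_km = row.get("fill_distance_km")
        out.append(
            DailyWeather(
                site_id=str(row["site_id"]),
                date=dt.date.fromisoformat(str(row["date"])[:10]),
                tmin=float(row["tmin_c"]),
                tmax=float(row["tmax_c"]),
                tmean=float(row["tmean_c"]),
                precip=float(row["precip_mm"]),
                rh_mean=None if rh is None or pd.isna(rh) else float(rh),
                source=str(row.get("source", "iot")),
                fill_station=None
                if fill_station is None or pd.isna(fill_station)
                else str(fill_station),
                fill_distance_km=None
                if fill_km is None or pd.isna(fill_km)
                else float(fill_km),
            )
        )
    out.sort(key=lambda d: d.date)
    return out


def read_daily_csv(path: str | Path) -> list[DailyWeather]:
    return frame_to_daily(pd.read_csv(path))


def write_daily_csv(series: Sequence[DailyWeather], path: str | Path) -> None:
    daily_to_frame(series).to_csv(path, index=False)


def read_station_registry(path: str | Path) -> list[StationMeta]:
    frame = pd.read_csv(path)
    return [
        StationMeta(
            station_id=str(r["station_id"]),
            lat=float(r["lat"]),
            lon=float(r["lon"]),
            elevation=float(r.get("elevation_m", 0.0)),
            kind=str(r.get("kind", "iot")),
            status=str(r.get("status", "online")),
        )
        for r in frame.to_dict("records")
    ]
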