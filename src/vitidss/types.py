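"""Core record types shared by the weather, disease and management engines.

All timestamps are UTC; daily records are keyed by UTC calendar date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

_VALID_SOURCES = ("iot", "national", "gap_filled", "synthetic")
_VALID_KINDS = ("iot", "national")
_VALID_STATUS = ("online", "offline")
_VALID_TREATMENTS = (
    "spray",
    "winter_pruning",
    "cane_removal",
    "fertilisation",
    "herbicide",
    "trimming",
    "irrigation",
    "other",
)


@dataclass(frozen=True)
class SubDailyObservation:
    """One sensor reading, nominally on a 30-minute cadence (48/day)."""

    station_id: str
    timestamp: dt.datetime
    temp: float
    rh: Optional[float] = None
    precip: float = 0.0
    wind_speed: Optional[float] = None
    pressure: Optional[float] = None
    co2: Optional[float] = None
    uv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rh is not None and not (0.0 <= self.rh <= 100.0):
            raise ValueError(f"rh {self.rh} outside [0, 100]")
        if self.precip < 0:
            raise ValueError(f"precip {self.precip} < 0")


@dataclass(frozen=True)
class StationMeta:
    station_id: str
    lat: float
    lon: float
    elevation: float = 0.0
    kind: str = "iot"
    status: str = "online"

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown station kind {self.kind!r}")
        if self.status not in _VALID_STATUS:
            raise ValueError(f"unknown station status {self.status!r}")


@dataclass(frozen=True)
class DailyWeather:
    """One quality-controlled day of weather for one site, with provenance.

    ``source`` records where the day came from; gap-filled days carry the
    donor station id and its great-circle distance from the site.
    """

    site_id: str
    date: dt.date
    tmin: float
    tmax: float
    tmean: float
    precip: float
    rh_mean: Optional[float] = None
    source: str = "iot"
    fill_station: Optional[str] = None
    fill_distance_km: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.tmin - 1e-9 <= self.tmean <= self.tmax + 1e-9):
            raise ValueError(
                f"{self.date}: requires tmin <= tmean <= tmax, got "
                f"{self.tmin}/{self.tmean}/{self.tmax}"
            )
        if self.precip < 0:
            raise ValueError(f"{self.date}: precip {self.precip} < 0")
        if self.source not in _VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "gap_filled" and (
            self.fill_station is None or self.fill_distance_km is None
        ):
            raise ValueError("gap_filled day must carry fill_station and fill_distance_km")


@dataclass
class StationNetwork:
    """A registry of stations plus their daily series, for gap-filling."""

    stations: list[StationMeta]
    daily: dict[str, list[DailyWeather]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.station_id for s in self.stations]
        if len(ids) != len(set(ids)):
            raise ValueError("station_id values must be unique")
        self._by_id = {s.station_id: s for s in self.stations}
        self._daily_by_date: dict[str, dict[dt.date, DailyWeather]] = {
            sid: {d.date: d for d in series} for sid, series in self.daily.items()
        }

    def station(self, station_id: str) -> StationMeta:
        return self._by_id[station_id]

    def day(self, station_id: str, date: dt.date) -> Optional[DailyWeather]:
        return self._daily_by_date.get(station_id, {}).get(date)


@dataclass(frozen=True)
class ManagementRecord:
    """One recorded field operation on a parcel."""

    parcel_id: str
    date: dt.date
    treatment: str
    variety: str = ""

    def __post_init__(self) -> None:
        if self.treatment not in _VALID_TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
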