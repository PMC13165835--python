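"""Dryness Index soil water balance and irrigation alerts.

The Dryness Index (DI) is a recursive daily soil water balance,

    DI_t = min(cap, DI_{t-1} + P_t - Tv_t - Es_t),

initialised at a 200 mm soil water reserve, where P is daily precipitation,
vine transpiration Tv = k1 * ETP, and soil evaporation
Es = (1 - k1) * ETP * min(P/5, 1) — soil only evaporates when rain has
wetted its surface. ETP is daily potential evapotranspiration by the
Thornthwaite formulation (mean temperature, photoperiod, annual heat
index). Days with DI below the operational threshold (50 mm) raise an
irrigation alert. No lower bound is applied to DI; deficits below zero are
reported as-is.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from calendar import monthrange
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import DailyWeather

logger = logging.getLogger(__name__)

#: default seasonal crop coefficient by month (Riou/Tonietto-style schedule)
DEFAULT_K1_SCHEDULE: dict[int, float] = {
    1: 0.1, 2: 0.1, 3: 0.1, 4: 0.1, 5: 0.3,
    6: 0.5, 7: 0.5, 8: 0.5, 9: 0.5, 10: 0.1, 11: 0.1, 12: 0.1,
}


@dataclass(frozen=True)
class DrynessParams:
    w0: float = 200.0
    cap: float = 200.0
    alert_threshold: float = 50.0
    k1_schedule: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_K1_SCHEDULE))
    es_rain_scale: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.w0 <= self.cap:
            raise ValueError("requires 0 < w0 <= cap")
        if self.alert_threshold >= self.cap:
            raise ValueError("alert_threshold must be below cap")
        if any(not 0.0 <= k <= 1.0 for k in self.k1_schedule.values()):
            raise ValueError("k1 coefficients must lie in [0, 1]")


@dataclass(frozen=True)
class DrynessEntry:
    date: dt.date
    di_mm: float
    etp_mm: float
    tv_mm: float
    es_mm: float
    alert: bool


@dataclass
class DrynessSeries:
    site_id: str
    entries: list[DrynessEntry]
    params: DrynessParams


@dataclass(frozen=True)
class AlertEvent:
    site_id: str
    date: dt.date
    value: float
    kind: str
    message: str


def annual_heat_index(monthly_tmean: Sequence[float]) -> float:
    """Thornthwaite annual heat index I = sum((max(0, T_m)/5)^1.514)."""
    if len(monthly_tmean) != 12:
        raise ValueError("need 12 monthly mean temperatures")
    return float(sum((max(0.0, t) / 5.0) ** 1.514 for t in monthly_tmean))


def photoperiod(lat: float, doy: int) -> float:
    """Day length in hours from the standard solar-declination formula."""
    if abs(lat) >= 66.5:
        raise ValueError("polar latitudes unsupported")
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(math.radians(lat)) * math.tan(decl)
    return (24.0 / math.pi) * math.acos(max(-1.0, min(1.0, x)))


def daily_thornthwaite_etp(
    tmean: float, heat_index: float, day_length_h: float, days_in_month: int
) -> float:
    """Daily potential evapotranspiration (mm/day), Thornthwaite.

    The monthly formulation 16*(10*T/I)^a is corrected by photoperiod
    (L/12) and divided by the number of days in the month.
    """
    if tmean <= 0.0:
        return 0.0
    if heat_index <= 0.0:
        raise ValueError("heat index must be positive when tmean > 0")
    i = heat_index
    a = 6.75e-7 * i**3 - 7.71e-5 * i**2 + 1.792e-2 * i + 0.49239
    monthly = 16.0 * (10.0 * tmean / i) ** a
    return monthly * (day_length_h / 12.0) / days_in_month


def di_step(
    di_prev: float, p: float, etp: float, k1: float, params: Optional[DrynessParams] = None
) -> tuple[float, float, float]:
    """One day of the DI recursion; returns (di, tv, es)."""
    if params is None:
        params = DrynessParams()
    tv = k1 * etp
    es = (1.0 - k1) * etp * min(p / params.es_rain_scale, 1.0)
    di = min(params.cap, di_prev + p - tv - es)
    return di, tv, es


def _monthly_means(daily: Sequence[DailyWeather]) -> dict[tuple[int, int], float]:
    sums: dict[tuple[int, int], list[float]] = defaultdict(list)
    for d in daily:
        sums[(d.date.year, d.date.month)].append(d.tmean)
    return {k: sum(v) / len(v) for k, v in sums.items()}


def _heat_index_by_year(daily: Sequence[DailyWeather]) -> dict[int, float]:
    """Per-year heat index from the series' own calendar-month means.

    Months absent in a year fall back to the climatological mean of that
    month across the series, then to the mean of whatever months exist.
    """
    by_month = _monthly_means(daily)
    clim: dict[int, list[float]] = defaultdict(list)
    for (_, m), t in by_month.items():
        clim[m].append(t)
    clim_mean = {m: sum(v) / len(v) for m, v in clim.items()}
    overall = sum(clim_mean.values()) / len(clim_mean)
    years = {d.date.year for d in daily}
    out = {}
    for y in years:
        months = []
        used_fallback = False
        for m in range(1, 13):
            if (y, m) in by_month:
                months.append(by_month[(y, m)])
            elif m in clim_mean:
                months.append(clim_mean[m])
                used_fallback = True
            else:
                months.append(overall)
                used_fallback = True
        if used_fallback:
            logger.info("heat index for %d uses climatological fill for absent months", y)
        out[y] = annual_heat_index(months)
    return out


def _check_contiguous(daily: Sequence[DailyWeather]) -> None:
    for prev, cur in zip(daily, daily[1:]):
        expected = prev.date + dt.timedelta(days=1)
        if cur.date != expected:
            raise ValueError(f"gap in daily series: missing {expected}")


def run_dryness_index(
    daily: Sequence[DailyWeather],
    lat: float,
    params: Optional[DrynessParams] = None,
    start: Optional[dt.date] = None,
) -> DrynessSeries:
    """Fold the DI recursion over a contiguous daily series.

    DI is initialised at ``params.w0`` on ``start`` (default: the first day
    of the series). The Thornthwaite heat index is computed per year from
    the same series. Alert flags mark days with DI strictly below the
    threshold.
    """
    if params is None:
        params = DrynessParams()
    series = sorted(daily, key=lambda d: d.date)
    if start is not None:
        series = [d for d in series if d.date >= start]
    if not series:
        raise ValueError("empty daily series")
    _check_contiguous(series)
    heat = _heat_index_by_year(series)

    entries: list[DrynessEntry] = []
    di = params.w0
    for d in series:
        dim = monthrange(d.date.year, d.date.month)[1]
        L = photoperiod(lat, d.date.timetuple().tm_yday)
        etp = daily_thornthwaite_etp(d.tmean, heat[d.date.year], L, dim) if d.tmean > 0 else 0.0
        k1 = params.k1_schedule.get(d.date.month, 0.1)
        di, tv, es = di_step(di, d.precip, etp, k1, params)
        entries.append(
            DrynessEntry(
                date=d.date,
                di_mm=di,
                etp_mm=etp,
                tv_mm=tv,
                es_mm=es,
                alert=di < params.alert_threshold,
            )
        )
    return DrynessSeries(site_id=series[0].site_id, entries=entries, params=params)


def seasonal_dryness_index(
    daily: Sequence[DailyWeather], lat: float, year: int,
    params: Optional[DrynessParams] = None,
) -> float:
    """Growing-season DI: recursion from Apr 1 at the full reserve, value on Sep 30.

    This is the seasonal bioclimatic-index variant of the daily engine.
    """
    window = [d for d in daily if dt.date(year, 4, 1) <= d.date <= dt.date(year, 9, 30)]
    if not window:
        raise ValueError(f"no data in Apr-Sep {year}")
    series = run_dryness_index(window, lat, params=params, start=dt.date(year, 4, 1))
    return series.entries[-1].di_mm


def irrigation_alerts(series: DrynessSeries) -> list[AlertEvent]:
    """One event per maximal run of consecutive alert days.

    Each event carries the run's first date and the minimum DI reached
    within the run.
    """
    events: list[AlertEvent] = []
    run_start: Optional[dt.date] = None
    run_min = float("inf")
    threshold = series.params.alert_threshold

    def flush() -> None:
        nonlocal run_start, run_min
        if run_start is not None:
            events.append(
                AlertEvent(
                    site_id=series.site_id,
                    date=run_start,
                    value=run_min,
                    kind="irrigation",
                    message=(
                        f"Dryness Index fell to {run_min:.1f} mm "
                        f"(threshold {threshold:.0f} mm): irrigation recommended"
                    ),
                )
            )
        run_start, run_min = None, float("inf")

    for e in series.entries:
        if e.alert:
            if run_start is None:
                run_start = e.date
            run_min = min(run_min, e.di_mm)
        else:
            flush()
    flush()
    return events
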