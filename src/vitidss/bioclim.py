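"""Annual viticultural bioclimatic indices and multi-model ensemble normals.

Indices follow the standard viticultural formulations: Winkler (growing
degree days base 10 °C, Apr 1 - Oct 31), biologically effective degree
days (daily contribution capped at 9 °C·day), Huglin heliothermal index
(Apr 1 - Sep 30, day-length coefficient K by latitude), cool-night index
(mean September tmin), growing-season mean temperature and precipitation,
De Martonne aridity index, the Branas hydrothermal product, a handful of
ETCCDI-style extremes, and the growing-season Dryness Index driven by the
irrigation engine's soil water balance.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import irrigation
from .types import DailyWeather


@dataclass(frozen=True)
class BioclimIndexSet:
    site_id: str
    year: int
    annual_t: float
    annual_p: float
    gst: float
    gsp: float
    gdd10: float
    winkler: float
    bedd: float
    huglin: float
    cool_night: float
    dryness: float
    branas: float
    de_martonne: float
    extremes: dict[str, float] = field(default_factory=dict)


def huglin_k(lat: float) -> float:
    """Huglin's stepwise day-length coefficient by absolute latitude."""
    alat = abs(lat)
    if alat <= 40.0:
        return 1.00
    for hi, k in ((42.0, 1.02), (44.0, 1.03), (46.0, 1.04), (48.0, 1.05), (50.0, 1.06)):
        if alat <= hi:
            return k
    return 1.06


def _window(daily: Sequence[DailyWeather], start: dt.date, end: dt.date) -> list[DailyWeather]:
    return [d for d in daily if start <= d.date <= end]


def _require_complete(daily: Sequence[DailyWeather], start: dt.date, end: dt.date) -> None:
    present = {d.date for d in daily}
    missing = []
    day = start
    while day <= end:
        if day not in present:
            missing.append(day)
        day += dt.timedelta(days=1)
    if missing:
        head = ", ".join(str(d) for d in missing[:5])
        raise ValueError(f"incomplete series, missing {len(missing)} day(s): {head}")


def gdd_sum(
    daily: Sequence[DailyWeather], base: float, window: tuple[dt.date, dt.date]
) -> float:
    """Sum of max(0, tmean - base) over the window; errors on missing days."""
    start, end = window
    _require_complete(daily, start, end)
    return float(sum(max(0.0, d.tmean - base) for d in _window(daily, start, end)))


def extremes_indices(daily: Sequence[DailyWeather]) -> dict[str, float]:
    """Six ETCCDI-style annual extremes from one civil year of daily data."""
    if not daily:
        raise ValueError("empty series")
    year = daily[0].date.year
    _require_complete(daily, dt.date(year, 1, 1), dt.date(year, 12, 31))
    days = sorted(daily, key=lambda d: d.date)
    cdd = run = 0
    for d in days:
        run = run + 1 if d.precip < 1.0 else 0
        cdd = max(cdd, run)
    return {
        "frost_days": float(sum(d.tmin < 0.0 for d in days)),
        "summer_days": float(sum(d.tmax > 25.0 for d in days)),
        "tropical_nights": float(sum(d.tmin > 20.0 for d in days)),
        "hot_days": float(sum(d.tmax > 35.0 for d in days)),
        "rx1day": float(max(d.precip for d in days)),
        "cdd": float(cdd),
    }


def compute_annual_indices(
    daily: Sequence[DailyWeather], lat: float, site_id: Optional[str] = None
) -> BioclimIndexSet:
    """All annual indices for one full civil year of daily weather.

    The growing season is the Northern-hemisphere Apr 1 - Oct 31 window
    (Huglin: Apr 1 - Sep 30); the dryness value is the irrigation engine's
    DI recursion started Apr 1 at the full 200 mm reserve, read on Sep 30.
    """
    if not daily:
        raise ValueError("empty series")
    year = daily[0].date.year
    _require_complete(daily, dt.date(year, 1, 1), dt.date(year, 12, 31))
    days = sorted(daily, key=lambda d: d.date)
    site = site_id if site_id is not None else days[0].site_id

    gs = _window(days, dt.date(year, 4, 1), dt.date(year, 10, 31))
    hug = _window(days, dt.date(year, 4, 1), dt.date(year, 9, 30))
    sept = [d for d in days if d.date.month == 9]

    annual_t = sum(d.tmean for d in days) / len(days)
    annual_p = sum(d.precip for d in days)
    winkler = sum(max(0.0, d.tmean - 10.0) for d in gs)
    bedd = sum(min(max(0.0, d.tmean - 10.0), 9.0) for d in gs)
    huglin = huglin_k(lat) * sum(
        max(0.0, ((d.tmean - 10.0) + (d.tmax - 10.0)) / 2.0) for d in hug
    )

    # Branas hydrothermal product over Apr-Aug: sum of monthly mean T x monthly P
    by_month: dict[int, list[DailyWeather]] = defaultdict(list)
    for d in days:
        by_month[d.date.month].append(d)
    branas = sum(
        (sum(x.tmean for x in by_month[m]) / len(by_month[m]))
        * sum(x.precip for x in by_month[m])
        for m in range(4, 9)
    )

    return BioclimIndexSet(
        site_id=site,
        year=year,
        annual_t=annual_t,
        annual_p=annual_p,
        gst=sum(d.tmean for d in gs) / len(gs),
        gsp=sum(d.precip for d in gs),
        gdd10=winkler,
        winkler=winkler,
        bedd=bedd,
        huglin=huglin,
        cool_night=sum(d.tmin for d in sept) / len(sept),
        dryness=irrigation.seasonal_dryness_index(days, lat, year),
        branas=branas,
        de_martonne=annual_p / (annual_t + 10.0),
        extremes=extremes_indices(days),
    )


@dataclass(frozen=True)
class EnsembleNormal:
    scenario: str
    period: tuple[int, int]
    index_name: str
    value: float
    n_models: int

    def __post_init__(self) -> None:
        if self.period[0] > self.period[1]:
            raise ValueError("period start must not exceed end")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def ensemble_normal(
    per_model_series: Mapping[str, Mapping[int, float]],
    scenario: str,
    period: tuple[int, int],
    index_name: str = "",
) -> EnsembleNormal:
    """Ensemble climate normal: mean over models of each model's period mean.

    Errors if any model is missing a year of the period.
    """
    start, end = period
    if not per_model_series:
        raise ValueError("no models supplied")
    model_means = []
    for model, series in per_model_series.items():
        values = []
        for year in range(start, end + 1):
            if year not in series:
                raise ValueError(f"model {model!r} missing year {year}")
            values.append(series[year])
        model_means.append(sum(values) / len(values))
    return EnsembleNormal(
        scenario=scenario,
        period=period,
        index_name=index_name,
        value=sum(model_means) / len(model_means),
        n_models=len(model_means),
    )


def indices_to_frame(index_sets: Sequence[BioclimIndexSet]) -> pd.DataFrame:
    """Tidy long-format table of index values (one row per site/year/index)."""
    rows = []
    for s in index_sets:
        scalars = {
            "annual_t": s.annual_t, "annual_p": s.annual_p, "gst": s.gst,
            "gsp": s.gsp, "gdd10": s.gdd10, "winkler": s.winkler,
            "bedd": s.bedd, "huglin": s.huglin, "cool_night": s.cool_night,
            "dryness": s.dryness, "branas": s.branas, "de_martonne": s.de_martonne,
            **s.extremes,
        }
        for name, value in scalars.items():
            rows.append({"site_id": s.site_id, "year": s.year, "index": name, "value": value})
    return pd.DataFrame(rows)
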