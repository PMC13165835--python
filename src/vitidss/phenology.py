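"""GDD-based phenological stage estimation and BBCH record validation.

Cumulative growing degree days (base 10 °C, from Jan 1) predict the dates
of calibrated BBCH stages. For dates beyond the last observation the daily
mean temperature is continued with climatological percentile scenarios:
the 25th / 50th / 75th daily percentiles across history give Cold, Median
and Hot continuations. A stage is flagged on the first day cumulative GDD
meets its threshold (inclusive). The shipped calibration is for the
autochthonous Montenegrin variety Vranac.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import DailyWeather

#: BBCH ranges accepted for field records, plus the calibrated stage codes
ALLOWED_BBCH_RANGES = ((11, 29), (53, 57), (60, 69), (71, 79), (81, 89), (91, 99))
CALIBRATED_BBCH = (7, 65, 81, 89)

SCENARIOS = ("cold", "median", "hot")
_PERCENTILE = {"cold": 25.0, "median": 50.0, "hot": 75.0}


@dataclass(frozen=True)
class PhenologyCalibration:
    variety: str
    base_temp: float = 10.0
    stages: tuple[tuple[int, float], ...] = ()  # (bbch_code, gdd_threshold)

    def __post_init__(self) -> None:
        thresholds = [t for _, t in self.stages]
        if any(b >= a for a, b in zip(thresholds[1:], thresholds)):
            raise ValueError("stage thresholds must be strictly increasing")
        if self.base_temp < 0:
            raise ValueError("base_temp must be >= 0")


def load_calibration(path: Optional[Union[str, Path]] = None) -> PhenologyCalibration:
    """Load a variety calibration from YAML (shipped Vranac by default)."""
    if path is None:
        text = resources.files("vitidss.data").joinpath("vranac.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return PhenologyCalibration(
        variety=str(raw["variety"]),
        base_temp=float(raw.get("base_temp", 10.0)),
        stages=tuple((int(s["bbch"]), float(s["gdd"])) for s in raw["stages"]),
    )


def _check_coverage(daily: Sequence[DailyWeather], start: dt.date, end: dt.date) -> None:
    present = {d.date for d in daily}
    missing = []
    day = start
    while day <= end:
        if day not in present:
            missing.append(day)
        day += dt.timedelta(days=1)
    if missing:
        head = ", ".join(str(d) for d in missing[:5])
        raise ValueError(f"missing {len(missing)} day(s) in series: {head}")


def cumulative_gdd(
    daily: Sequence[DailyWeather], calib: PhenologyCalibration, through: dt.date
) -> float:
    """Sum of max(0, tmean - base) from Jan 1 through ``through``."""
    start = dt.date(through.year, 1, 1)
    _check_coverage(daily, start, through)
    return float(
        sum(max(0.0, d.tmean - calib.base_temp) for d in daily if start <= d.date <= through)
    )


@dataclass(frozen=True)
class ScenarioSeries:
    """A full-year daily tmean continuation keyed by (month, day)."""

    scenario: str
    daily_tmean: dict[tuple[int, int], float]

    def tmean_on(self, date: dt.date) -> float:
        key = (date.month, date.day)
        if key == (2, 29):  # leap day shares the Feb 28 climatology
            key = (2, 28)
        return self.daily_tmean[key]


def build_climatology_scenarios(
    historical_daily: Sequence[DailyWeather],
) -> dict[str, ScenarioSeries]:
    """Cold/Median/Hot continuation series from >= 3 years of daily history.

    Per calendar day, the 25th/50th/75th percentile of tmean across years
    (linear interpolation); Feb 29 values are merged into Feb 28.
    """
    years = {d.date.year for d in historical_daily}
    if len(years) < 3:
        raise ValueError(f"need >= 3 years of history, got {len(years)}")
    samples: dict[tuple[int, int], list[float]] = {}
    for d in historical_daily:
        key = (d.date.month, d.date.day)
        if key == (2, 29):
            key = (2, 28)
        samples.setdefault(key, []).append(d.tmean)
    out = {}
    for name in SCENARIOS:
        q = _PERCENTILE[name]
        out[name] = ScenarioSeries(
            scenario=name,
            daily_tmean={
                k: float(np.percentile(v, q, method="linear")) for k, v in samples.items()
            },
        )
    return out


@dataclass(frozen=True)
class StageForecast:
    variety: str
    bbch: int
    scenario: str  # observed | cold | median | hot
    predicted_date: Optional[dt.date]  # None = not reached by Dec 31
    gdd_at_forecast: float

    @property
    def reached(self) -> bool:
        return self.predicted_date is not None


def forecast_stage_dates(
    observed: Sequence[DailyWeather],
    scenarios: dict[str, ScenarioSeries],
    calib: PhenologyCalibration,
) -> list[StageForecast]:
    """Predict stage dates by blending observations with scenario continuations.

    Cumulative GDD runs over the observed series (Jan 1 .. last observed
    day); each scenario appends its climatological tmean for the remaining
    days of the year. Stages crossed within the observations are reported
    once with scenario="observed"; later stages get one forecast per
    scenario; stages whose threshold is not met by Dec 31 report no date.
    """
    series = sorted(observed, key=lambda d: d.date)
    if not series:
        raise ValueError("empty observed series")
    year = series[0].date.year
    last = series[-1].date
    _check_coverage(series, dt.date(year, 1, 1), last)

    # cumulative GDD after each observed day
    obs_cum: list[tuple[dt.date, float]] = []
    total = 0.0
    for d in series:
        total += max(0.0, d.tmean - calib.base_temp)
        obs_cum.append((d.date, total))

    forecasts: list[StageForecast] = []
    for bbch, threshold in calib.stages:
        crossed = next((dc for dc in obs_cum if dc[1] >= threshold), None)
        if crossed is not None:
            forecasts.append(
                StageForecast(
                    variety=calib.variety,
                    bbch=bbch,
                    scenario="observed",
                    predicted_date=crossed[0],
                    gdd_at_forecast=crossed[1],
                )
            )
            continue
        for name in SCENARIOS:
            scen = scenarios[name]
            cum = total
            day = last
            predicted = None
            while day < dt.date(year, 12, 31):
                day += dt.timedelta(days=1)
                cum += max(0.0, scen.tmean_on(day) - calib.base_temp)
                if cum >= threshold:
                    predicted = day
                    break
            # unreached stages report the scenario's end-of-year cumulative GDD
            gdd_at = cum
            forecasts.append(
                StageForecast(
                    variety=calib.variety,
                    bbch=bbch,
                    scenario=name,
                    predicted_date=predicted,
                    gdd_at_forecast=gdd_at,
                )
            )
    return forecasts


@dataclass(frozen=True)
class PhenologyObservation:
    parcel_id: str
    date: dt.date
    variety: str
    bbch: int
    photo_ref: Optional[str] = None


@dataclass(frozen=True)
class ValidationResult:
    accepted: bool
    reason: str = ""


def validate_phenology_record(
    obs: PhenologyObservation,
    existing: Sequence[PhenologyObservation] = (),
    today: Optional[dt.date] = None,
) -> ValidationResult:
    """Validate a field BBCH record; rejection is a report, not an exception."""
    in_range = any(lo <= obs.bbch <= hi for lo, hi in ALLOWED_BBCH_RANGES)
    if not in_range and obs.bbch not in CALIBRATED_BBCH:
        return ValidationResult(False, f"BBCH {obs.bbch} outside all allowed stage ranges")
    if today is not None and obs.date > today:
        return ValidationResult(False, f"observation date {obs.date} lies in the future")
    for e in existing:
        if (e.parcel_id, e.variety, e.bbch, e.date) == (
            obs.parcel_id,
            obs.variety,
            obs.bbch,
            obs.date,
        ):
            return ValidationResult(False, "duplicate record (parcel, variety, bbch, date)")
    return ValidationResult(True)


def read_phenology_csv(path: Union[str, Path]) -> list[PhenologyObservation]:
    frame = pd.read_csv(path)
    out = []
    for r in frame.to_dict("records"):
        photo = r.get("photo_ref")
        out.append(
            PhenologyObservation(
                parcel_id=str(r["parcel_id"]),
                date=dt.date.fromisoformat(str(r["date"])[:10]),
                variety=str(r["variety"]),
                bbch=int(r["bbch"]),
                photo_ref=None if photo is None or pd.isna(photo) else str(photo),
            )
        )
    return out
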