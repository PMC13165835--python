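"""Minimal process-based grapevine growth and yield simulator.

Daily biomass gain is intercepted photosynthetically active radiation
(Beer-Lambert canopy interception over a GDD-driven leaf area ramp) times
radiation-use efficiency, down-regulated by a linear Fraction of
Transpirable Soil Water (FTSW) stress ramp. After anthesis a fixed
fraction of new assimilate is allocated to fruit; final yield is the fruit
dry biomass when cumulative GDD reaches physiological maturity. Incident
radiation is estimated from the diurnal temperature range
(Hargreaves-Samani), and the water balance is driven by the Thornthwaite
ETP of the irrigation engine. Management inputs matter: trimming caps leaf
area from its date onward, recorded irrigation events add water.

Every functional form here (linear LAI ramp, linear FTSW ramp, constant
partition coefficient, Hargreaves radiation) is a deliberately simple
default chosen for transparency and testability; all constants live in
:class:`VineSimConfig`. The phenological anchors default to the Vranac GDD
calibration (anthesis 492, maturity 2188 °C·day).
"""

from __future__ import annotations

import datetime as dt
import math
from calendar import monthrange
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .irrigation import _heat_index_by_year, daily_thornthwaite_etp, photoperiod
from .types import DailyWeather, ManagementRecord

#: solar constant, MJ m-2 min-1 (standard value)
GSC = 0.0820


@dataclass(frozen=True)
class VineSimConfig:
    rue: float = 1.0  # g dry mass per MJ intercepted PAR
    k_ext: float = 0.5  # canopy light-extinction coefficient
    lai_max: float = 3.0  # m2/m2
    lai_growth_rate: float = 0.005  # m2/m2 per degree-day
    ttsw: float = 150.0  # total transpirable soil water, mm
    ftsw_crit: float = 0.4  # stress onset fraction
    fruit_partition: float = 0.5  # post-anthesis assimilate share to fruit
    anthesis_gdd: float = 492.0  # degree-days, Vranac full flowering
    maturity_gdd: float = 2188.0  # degree-days, Vranac harvest ripeness
    trim_lai_cap: Optional[float] = None  # m2/m2 while trimmed
    irrigation_mm_per_event: float = 20.0

    def __post_init__(self) -> None:
        for name in ("rue", "k_ext", "lai_max", "lai_growth_rate", "ttsw",
                     "anthesis_gdd", "maturity_gdd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.ftsw_crit < 1.0:
            raise ValueError("ftsw_crit must lie in (0, 1)")
        if not 0.0 <= self.fruit_partition <= 1.0:
            raise ValueError("fruit_partition must lie in [0, 1]")


@dataclass(frozen=True)
class VineDailyState:
    date: dt.date
    lai: float = 0.0
    biomass: float = 0.0
    fruit_biomass: float = 0.0
    atsw: float = 150.0
    ftsw: float = 1.0
    gdd_cum: float = 0.0


def extraterrestrial_radiation(lat: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ/m2/day), FAO-56 formulation."""
    phi = math.radians(lat)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(decl))))
    return (
        (24.0 * 60.0 / math.pi)
        * GSC
        * dr
        * (
            ws * math.sin(phi) * math.sin(decl)
            + math.cos(phi) * math.cos(decl) * math.sin(ws)
        )
    )


def estimate_radiation(day: DailyWeather, lat: float) -> float:
    """Incident PAR (MJ/m2/day) from the diurnal temperature range.

    Hargreaves-Samani global radiation Rs = 0.16 sqrt(tmax - tmin) * Ra;
    PAR is taken as half of Rs.
    """
    if day.tmax < day.tmin:
        raise ValueError("tmax < tmin")
    ra = extraterrestrial_radiation(lat, day.date.timetuple().tm_yday)
    rs = 0.16 * math.sqrt(day.tmax - day.tmin) * ra
    return 0.5 * rs


def ftsw_stress(ftsw: float, ftsw_crit: float) -> float:
    """Linear stress ramp: 1 above the critical fraction, ftsw/crit below."""
    return min(1.0, ftsw / ftsw_crit)


def step_vine_day(
    state: VineDailyState,
    day: DailyWeather,
    par: float,
    etp: float,
    irrigation_mm: float = 0.0,
    trimmed: bool = False,
    cfg: Optional[VineSimConfig] = None,
) -> VineDailyState:
    """Advance the vine one day.

    Leaf area grows with degree-days toward lai_max (capped while
    trimmed); biomass gain is RUE x intercepted PAR x water stress; fruit
    receives its partition share once cumulative GDD passes anthesis; the
    soil bucket gains rain and irrigation and loses canopy-scaled
    transpiration demand modulated by the same stress factor.
    """
    if cfg is None:
        cfg = VineSimConfig()
    dgdd = max(0.0, day.tmean - 10.0)
    gdd_cum = state.gdd_cum + dgdd

    lai_cap = cfg.lai_max
    if trimmed and cfg.trim_lai_cap is not None:
        lai_cap = min(lai_cap, cfg.trim_lai_cap)
    lai = min(lai_cap, state.lai + cfg.lai_growth_rate * dgdd)

    interception = 1.0 - math.exp(-cfg.k_ext * lai)
    stress = ftsw_stress(state.ftsw, cfg.ftsw_crit)
    db = cfg.rue * par * interception * stress
    biomass = state.biomass + db
    fruit = state.fruit_biomass
    if gdd_cum >= cfg.anthesis_gdd:
        fruit += cfg.fruit_partition * db

    demand = etp * interception
    atsw = min(cfg.ttsw, max(0.0, state.atsw + day.precip + irrigation_mm - demand * stress))
    return VineDailyState(
        date=day.date,
        lai=lai,
        biomass=biomass,
        fruit_biomass=fruit,
        atsw=atsw,
        ftsw=atsw / cfg.ttsw,
        gdd_cum=gdd_cum,
    )


@dataclass
class YieldResult:
    trajectory: list[VineDailyState]
    final_yield: float  # g/m2 fruit dry biomass
    maturity_date: Optional[dt.date]
    immature: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [s.date.isoformat() for s in self.trajectory],
                "lai": [s.lai for s in self.trajectory],
                "biomass": [s.biomass for s in self.trajectory],
                "fruit_biomass": [s.fruit_biomass for s in self.trajectory],
                "ftsw": [s.ftsw for s in self.trajectory],
                "gdd_cum": [s.gdd_cum for s in self.trajectory],
            }
        )


def run_yield_simulation(
    daily: Sequence[DailyWeather],
    management: Sequence[ManagementRecord] = (),
    cfg: Optional[VineSimConfig] = None,
    lat: float = 42.44,
) -> YieldResult:
    """Fold the daily step over one season; yield at first maturity crossing.

    Trimming records activate the LAI cap from their date onward;
    irrigation records add ``irrigation_mm_per_event`` on their date. If
    maturity GDD is never reached the season-end fruit biomass is reported
    and flagged immature.
    """
    if cfg is None:
        cfg = VineSimConfig()
    series = sorted(daily, key=lambda d: d.date)
    if not series:
        raise ValueError("empty daily series")
    for prev, cur in zip(series, series[1:]):
        if cur.date != prev.date + dt.timedelta(days=1):
            raise ValueError(f"gap in daily series: missing {prev.date + dt.timedelta(days=1)}")

    heat = _heat_index_by_year(series)
    trim_from = min(
        (m.date for m in management if m.treatment == "trimming"), default=None
    )
    irrigation_days: dict[dt.date, float] = {}
    for m in management:
        if m.treatment == "irrigation":
            irrigation_days[m.date] = (
                irrigation_days.get(m.date, 0.0) + cfg.irrigation_mm_per_event
            )

    state = VineDailyState(date=series[0].date, atsw=cfg.ttsw, ftsw=1.0)
    trajectory: list[VineDailyState] = []
    maturity_date: Optional[dt.date] = None
    final_yield: Optional[float] = None
    for d in series:
        par = estimate_radiation(d, lat)
        dim = monthrange(d.date.year, d.date.month)[1]
        L = photoperiod(lat, d.date.timetuple().tm_yday)
        etp = (
            daily_thornthwaite_etp(d.tmean, heat[d.date.year], L, dim)
            if d.tmean > 0
            else 0.0
        )
        state = step_vine_day(
            state,
            d,
            par=par,
            etp=etp,
            irrigation_mm=irrigation_days.get(d.date, 0.0),
            trimmed=trim_from is not None and d.date >= trim_from,
            cfg=cfg,
        )
        trajectory.append(state)
        if maturity_date is None and state.gdd_cum >= cfg.maturity_gdd:
            maturity_date = d.date
            final_yield = state.fruit_biomass
    if final_yield is None:
        final_yield = trajectory[-1].fruit_biomass
    return YieldResult(
        trajectory=trajectory,
        final_yield=final_yield,
        maturity_date=maturity_date,
        immature=maturity_date is None,
    )
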