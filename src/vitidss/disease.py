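"""Goidanich downy-mildew risk accumulation and disease alerts.

The model runs in two sequential phases. Primary infection onset is the
'3-10 rule': daily precipitation exceeding 10 mm, mean air temperature
above 10 °C and vine shoot length beyond 10 cm (all strict comparisons).
From the day after the rule first fires, the cumulative Goidanich index
accumulates daily,

    GI_t = min(100, GI_{t-1} + f(T_t, RH_t)),

with f a temperature x relative-humidity development-rate table for
*Plasmopara viticola*. GI above 50 % raises a treatment alert. Recorded
spray events (manual mode) reset GI to zero; automatic mode assumes a
treatment the day after the threshold is first exceeded; hybrid mode
applies both rules.
"""

from __future__ import annotations

import bisect
import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .irrigation import AlertEvent
from .types import DailyWeather, ManagementRecord


@dataclass(frozen=True)
class IncrementTable:
    """Left-closed right-open (temp, RH) bins mapping to %/day increments."""

    temp_edges: tuple[float, ...]
    rh_edges: tuple[float, ...]
    increments: tuple[tuple[float, ...], ...]  # [temp bin][rh bin]

    def __post_init__(self) -> None:
        if list(self.temp_edges) != sorted(self.temp_edges) or len(set(self.temp_edges)) != len(
            self.temp_edges
        ):
            raise ValueError("temp_edges must be strictly increasing (bins cannot overlap)")
        if list(self.rh_edges) != sorted(self.rh_edges) or len(set(self.rh_edges)) != len(
            self.rh_edges
        ):
            raise ValueError("rh_edges must be strictly increasing (bins cannot overlap)")
        n_t, n_rh = len(self.temp_edges) - 1, len(self.rh_edges) - 1
        if len(self.increments) != n_t or any(len(r) != n_rh for r in self.increments):
            raise ValueError("increment matrix shape must match bin counts")
        if any(v < 0 for row in self.increments for v in row):
            raise ValueError("increments must be non-negative")

    def lookup(self, tmean: float, rh: float) -> float:
        """Increment for (tmean, rh); 0 outside all bins."""
        if not (self.temp_edges[0] <= tmean < self.temp_edges[-1]):
            return 0.0
        if not (self.rh_edges[0] <= rh < self.rh_edges[-1]):
            return 0.0
        i = bisect.bisect_right(self.temp_edges, tmean) - 1
        j = bisect.bisect_right(self.rh_edges, rh) - 1
        return self.increments[i][j]


def load_increment_table(path: Optional[Union[str, Path]] = None) -> IncrementTable:
    """Load an increment table from YAML (shipped default when path is None)."""
    if path is None:
        text = resources.files("vitidss.data").joinpath("goidanich_table.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return IncrementTable(
        temp_edges=tuple(float(x) for x in raw["temp_edges"]),
        rh_edges=tuple(float(x) for x in raw["rh_edges"]),
        increments=tuple(tuple(float(v) for v in row) for row in raw["increments"]),
    )


@dataclass(frozen=True)
class GoidanichParams:
    rain_activation: float = 10.0
    temp_activation: float = 10.0
    shoot_activation: float = 10.0
    alert_threshold: float = 50.0
    cap: float = 100.0
    increment_table: Optional[IncrementTable] = None
    mode: str = "hybrid"

    def __post_init__(self) -> None:
        if not 0.0 < self.alert_threshold < self.cap:
            raise ValueError("requires 0 < alert_threshold < cap")
        if self.mode not in ("automatic", "manual", "hybrid"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def table(self) -> IncrementTable:
        return self.increment_table if self.increment_table is not None else load_increment_table()


@dataclass(frozen=True)
class ShootRule:
    """How the 10 cm shoot-length condition is decided.

    kind="observed": satisfied from a user-recorded date onward;
    kind="gdd": satisfied once cumulative GDD (base 10 °C) from the series
    start reaches ``gdd_threshold``; kind="always": unconditionally true.
    """

    kind: str = "gdd"
    observed_date: Optional[dt.date] = None
    gdd_threshold: float = 150.0

    def __post_init__(self) -> None:
        if self.kind not in ("observed", "gdd", "always"):
            raise ValueError(f"unknown shoot rule {self.kind!r}")
        if self.kind == "observed" and self.observed_date is None:
            raise ValueError("observed shoot rule needs observed_date")


def check_primary_infection_rule(
    day: DailyWeather, shoot_ok: bool, params: Optional[GoidanichParams] = None
) -> bool:
    """The 3-10 rule, all comparisons strict."""
    if params is None:
        params = GoidanichParams()
    return (
        day.precip > params.rain_activation
        and day.tmean > params.temp_activation
        and shoot_ok
    )


def goidanich_increment(tmean: float, rh_mean: Optional[float], table: IncrementTable) -> float:
    if rh_mean is None:
        return 0.0
    return table.lookup(tmean, rh_mean)


@dataclass(frozen=True)
class GoidanichDay:
    date: dt.date
    gi: float
    activated: bool
    alert: bool
    reset: bool


def _check_contiguous(daily: Sequence[DailyWeather]) -> None:
    for prev, cur in zip(daily, daily[1:]):
        expected = prev.date + dt.timedelta(days=1)
        if cur.date != expected:
            raise ValueError(f"gap in daily series: missing {expected}")


def run_goidanich(
    daily: Sequence[DailyWeather],
    management: Sequence[ManagementRecord] = (),
    shoot_rule: Optional[ShootRule] = None,
    params: Optional[GoidanichParams] = None,
) -> list[GoidanichDay]:
    """Run the two-phase Goidanich model over a contiguous daily series.

    GI stays at 0 until the 3-10 rule first fires; activation is latched
    for the season (resets zero GI but do not de-activate). Increments are
    applied from the day after activation. A reset zeroes GI at the end of
    its day, so an automatic-mode alert is observable for exactly one day
    before the assumed treatment takes effect.
    """
    if params is None:
        params = GoidanichParams()
    if shoot_rule is None:
        shoot_rule = ShootRule()
    series = sorted(daily, key=lambda d: d.date)
    if not series:
        return []
    _check_contiguous(series)
    table = params.table()
    spray_dates = {m.date for m in management if m.treatment == "spray"}

    out: list[GoidanichDay] = []
    gi = 0.0
    activated = False
    gdd_cum = 0.0
    pending_auto_reset = False
    for d in series:
        gdd_cum += max(0.0, d.tmean - 10.0)
        if shoot_rule.kind == "always":
            shoot_ok = True
        elif shoot_rule.kind == "observed":
            shoot_ok = d.date >= shoot_rule.observed_date  # type: ignore[operator]
        else:
            shoot_ok = gdd_cum >= shoot_rule.gdd_threshold

        if activated:
            gi = min(params.cap, gi + goidanich_increment(d.tmean, d.rh_mean, table))
        elif check_primary_infection_rule(d, shoot_ok, params):
            activated = True  # accumulation starts the following day

        alert = gi > params.alert_threshold
        reset = False
        if params.mode in ("manual", "hybrid") and d.date in spray_dates:
            reset = True
        if params.mode in ("automatic", "hybrid") and pending_auto_reset:
            reset = True
        pending_auto_reset = (
            params.mode in ("automatic", "hybrid") and alert and not reset
        )
        if reset:
            gi = 0.0
            alert = False
        out.append(GoidanichDay(date=d.date, gi=gi, activated=activated, alert=alert, reset=reset))
    return out


def disease_alerts(series: Sequence[GoidanichDay], parcel_id: str = "") -> list[AlertEvent]:
    """One event at the first day of each maximal run of alert days."""
    events: list[AlertEvent] = []
    in_run = False
    for day in series:
        if day.alert and not in_run:
            events.append(
                AlertEvent(
                    site_id=parcel_id,
                    date=day.date,
                    value=day.gi,
                    kind="disease",
                    message=(
                        f"Downy-mildew risk index reached {day.gi:.1f}% "
                        f"(threshold 50%): timely treatment application recommended"
                    ),
                )
            )
        in_run = day.alert
    return events


def risk_to_frame(series: Sequence[GoidanichDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in series],
            "gi": [d.gi for d in series],
            "activated": [d.activated for d in series],
            "alert": [d.alert for d in series],
            "reset": [d.reset for d in series],
        }
    )


def read_management_csv(path: Union[str, Path]) -> list[ManagementRecord]:
    frame = pd.read_csv(path)
    return [
        ManagementRecord(
            parcel_id=str(r["parcel_id"]),
            date=dt.date.fromisoformat(str(r["date"])[:10]),
            treatment=str(r["treatment"]),
            variety=str(r.get("variety", "") or ""),
        )
        for r in frame.to_dict("records")
    ]
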