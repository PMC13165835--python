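"""Alert-message rendering and tabular record export."""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .irrigation import AlertEvent
from .phenology import PhenologyObservation, StageForecast
from .types import ManagementRecord

logger = logging.getLogger(__name__)

_THRESHOLDS = {"irrigation": 50.0, "disease": 50.0}


@dataclass(frozen=True)
class AlertMessage:
    site_id: str
    kind: str  # irrigation | disease | phenology
    date: dt.date
    severity: str  # info | warning
    body: str
    payload: dict = field(default_factory=dict)
    parcel_id: str = ""


def render_alert(event: Union[AlertEvent, StageForecast]) -> AlertMessage:
    """Render an engine event into a user-facing notification.

    Irrigation and disease events become warnings carrying the triggering
    value and threshold; phenology stage forecasts become informational
    messages naming the BBCH stage and scenario.
    """
    if isinstance(event, AlertEvent):
        if event.kind not in _THRESHOLDS:
            raise ValueError(f"unknown alert kind {event.kind!r}")
        threshold = _THRESHOLDS[event.kind]
        return AlertMessage(
            site_id=event.site_id,
            kind=event.kind,
            date=event.date,
            severity="warning",
            body=event.message,
            payload={"value": event.value, "threshold": threshold},
        )
    if isinstance(event, StageForecast):
        when = event.predicted_date.isoformat() if event.predicted_date else "not reached"
        body = (
            f"{event.variety} BBCH {event.bbch:02d} expected {when} "
            f"({event.scenario} scenario, {event.gdd_at_forecast:.0f} degree-days)"
        )
        return AlertMessage(
            site_id=event.variety,
            kind="phenology",
            date=event.predicted_date or dt.date.max,
            severity="info",
            body=body,
            payload={
                "bbch": event.bbch,
                "scenario": event.scenario,
                "gdd": event.gdd_at_forecast,
            },
        )
    raise ValueError(f"cannot render event of type {type(event).__name__}")


def _records_frame(
    records: Sequence[Union[PhenologyObservation, ManagementRecord]],
    window: tuple[dt.date, dt.date],
) -> pd.DataFrame:
    start, end = window
    if start > end:
        raise ValueError("window start after end")
    rows = [asdict(r) for r in records if start <= r.date <= end]
    if not rows:
        logger.warning("no records inside window %s..%s", start, end)
        if records:
            return pd.DataFrame(columns=list(asdict(records[0]).keys()))
        return pd.DataFrame()
    frame = pd.DataFrame(rows)
    frame["date"] = frame["date"].map(lambda d: d.isoformat())
    return frame


def export_records(
    records: Sequence[Union[PhenologyObservation, ManagementRecord]],
    window: tuple[dt.date, dt.date],
    path: Union[str, Path],
    format: str = "csv",
) -> Path:
    """Export records inside the window as CSV or XLSX; returns the path."""
    path = Path(path)
    frame = _records_frame(records, window)
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "xlsx":
        sheet = type(records[0]).__name__ if records else "records"
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            frame.to_excel(writer, index=False, sheet_name=sheet)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
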