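"""Line-delimited event-log and tabular dataset I/O.

Event logs are UTF-8 JSON lines.  The first line is a header carrying the
schema version; every following line is one record typed by its ``kind``
field (``fix`` | ``report`` | ``reset``).  Timestamps are ISO-8601 with an
explicit UTC offset.  write -> read round-trips are bit-stable.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .engine import (
    Event,
    LocationFix,
    ResetCommand,
    SmokingReport,
    TriggerDecision,
)
from .geo import GeoPoint
from .stats import OutcomeRecord

__all__ = [
    "SCHEMA",
    "EventLogError",
    "write_event_log",
    "read_event_log",
    "write_decisions_csv",
    "write_participants_csv",
    "read_participants_csv",
]

SCHEMA = "jitaikit-events/1"


class EventLogError(ValueError):
    """Malformed or unreadable event log; message names the offending line."""


def _dump(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _event_to_json(event: Event) -> dict:
    if isinstance(event, LocationFix):
        return {
            "kind": "fix",
            "t": event.timestamp.isoformat(),
            "lat": event.point.latitude,
            "lon": event.point.longitude,
            "acc": event.accuracy_m,
        }
    if isinstance(event, SmokingReport):
        rec = {
            "kind": "report",
            "t": event.timestamp.isoformat(),
            "urge": event.urge_strength,
            "stress": event.stress,
            "mood": event.mood,
            "situation": event.situation.value,
            "others": event.others_present,
            "lapse": event.is_lapse,
        }
        if event.point is not None:
            rec["lat"] = event.point.latitude
            rec["lon"] = event.point.longitude
        return rec
    if isinstance(event, ResetCommand):
        return {
            "kind": "reset",
            "t": event.timestamp.isoformat(),
            "quit_date": event.new_quit_date.isoformat(),
        }
    raise TypeError(f"unknown event type {type(event).__name__}")


def _event_from_json(rec: dict) -> Event:
    kind = rec.get("kind")
    ts = datetime.fromisoformat(rec["t"])
    if kind == "fix":
        return LocationFix(ts, GeoPoint(rec["lat"], rec["lon"]), rec.get("acc", 0.0))
    if kind == "report":
        point = (
            GeoPoint(rec["lat"], rec["lon"]) if "lat" in rec and "lon" in rec else None
        )
        return SmokingReport(
            timestamp=ts,
            point=point,
            urge_strength=rec["urge"],
            stress=rec["stress"],
            mood=rec["mood"],
            situation=rec["situation"],
            others_present=rec["others"],
            is_lapse=rec.get("lapse", False),
        )
    if kind == "reset":
        return ResetCommand(ts, date.fromisoformat(rec["quit_date"]))
    raise EventLogError(f"unknown record kind {kind!r}")


def write_event_log(path: Union[str, Path], events: Iterable[Event]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_dump({"kind": "header", "schema": SCHEMA}) + "\n")
        for event in events:
            fh.write(_dump(_event_to_json(event)) + "\n")


def read_event_log(path: Union[str, Path]) -> list[Event]:
    """Read a typed, time-ordered event stream; errors name the line number."""
    path = Path(path)
    events: list[Event] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise EventLogError(f"{path}: empty file (missing header)")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise EventLogError(f"{path}:1: malformed header: {exc}") from None
    if header.get("schema") != SCHEMA:
        raise EventLogError(f"{path}:1: unknown schema {header.get('schema')!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            events.append(_event_from_json(json.loads(line)))
        except (EventLogError, KeyError, ValueError) as exc:
            raise EventLogError(f"{path}:{lineno}: {exc}") from None
    return events


def write_decisions_csv(path: Union[str, Path], decisions: Sequence[TriggerDecision]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "fence_id", "reason", "fired"])
        for d in decisions:
            writer.writerow(
                [d.time.isoformat(), d.fence_id or "", d.reason.value, str(d.fired).lower()]
            )


_BOOL = {"true": True, "false": False, "": None}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    return str(value)


_PARTICIPANT_COLUMNS = [
    "id",
    "arm",
    "heavy_smoker",
    "low_ses",
    "cigarettes_per_day",
    "installed",
    "engagement_days",
    "true_quit_outcome_6m",
    "lapse_first_2w",
    "self_report_prolonged",
    "self_report_7day_6m",
    "self_report_7day_6w",
    "cotinine_ng_ml",
    "anabasine_ng_ml",
    "nicotine_substitution_use",
    "withdrawn",
]


def write_participants_csv(path: Union[str, Path], dataset) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PARTICIPANT_COLUMNS)
        for p in dataset.participants:
            r = p.record
            writer.writerow(
                [
                    p.id,
                    p.arm,
                    _fmt(p.strata[0]),
                    _fmt(p.strata[1]),
                    f"{p.profile.cigarettes_per_day:.2f}",
                    _fmt(p.installed),
                    f"{p.engagement_days:.2f}",
                    _fmt(p.true_quit_outcome_6m),
                    _fmt(p.lapse_first_2w),
                    _fmt(r.self_report_prolonged),
                    _fmt(r.self_report_7day_6m),
                    _fmt(r.self_report_7day_6w),
                    _fmt(r.cotinine_ng_ml),
                    _fmt(r.anabasine_ng_ml),
                    _fmt(r.nicotine_substitution_use),
                    _fmt(r.withdrawn),
                ]
            )


def read_participants_csv(path: Union[str, Path]) -> list[dict]:
    """Rows as dicts; the OutcomeRecord fields are parsed into a ``record`` key."""
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _PARTICIPANT_COLUMNS:
            raise EventLogError(f"{path}: unexpected participant columns")
        for raw in reader:
            def fnum(key: str) -> Optional[float]:
                return float(raw[key]) if raw[key] != "" else None

            record = OutcomeRecord(
                arm=raw["arm"],
                self_report_prolonged=_BOOL[raw["self_report_prolonged"]],
                self_report_7day_6m=_BOOL[raw["self_report_7day_6m"]],
                self_report_7day_6w=_BOOL[raw["self_report_7day_6w"]],
                cotinine_ng_ml=fnum("cotinine_ng_ml"),
                anabasine_ng_ml=fnum("anabasine_ng_ml"),
                nicotine_substitution_use=bool(_BOOL[raw["nicotine_substitution_use"]]),
                withdrawn=bool(_BOOL[raw["withdrawn"]]),
            )
            rows.append(
                {
                    "id": raw["id"],
                    "arm": raw["arm"],
                    "heavy_smoker": _BOOL[raw["heavy_smoker"]],
                    "low_ses": _BOOL[raw["low_ses"]],
                    "cigarettes_per_day": float(raw["cigarettes_per_day"]),
                    "installed": _BOOL[raw["installed"]],
                    "engagement_days": float(raw["engagement_days"]),
                    "true_quit_outcome_6m": _BOOL[raw["true_quit_outcome_6m"]],
                    "lapse_first_2w": _BOOL[raw["lapse_first_2w"]],
                    "record": record,
                }
            )
    return rows
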