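"""Line-delimited JSON event logs: schema validation, reading, writing.

One JSON object per line with canonical key order, so rewriting an unchanged
stream is byte-identical.  Dates are ISO-8601 days: the coaching logic is
day-granular.  Events for a patient must appear in non-decreasing date order.
"""

from __future__ import annotations

import datetime as dt
import io
import json
from pathlib import Path
from typing import IO, Iterable, Iterator

from .model import (
    BehaviorId,
    EventLogError,
    EventType,
    FollowupAnswer,
    JourneyEvent,
    MinutesBand,
    NON_START_REASONS,
    ValidationError,
)

_BAND_NAMES = {b.name.lower(): b for b in MinutesBand}
_EFFORTS = ("too_easy", "just_right", "too_hard")

#: Required payload fields per event type (name -> validator).
_SCHEMAS: dict[EventType, dict[str, object]] = {
    EventType.QUESTIONNAIRE_RESPONSE: {"item_id": str, "answer_index": int},
    EventType.IC_RATING: {"importance": int, "confidence": int},
    EventType.EDUCATION_VIEWED: {"content_id": str},
    # goal_set payload is behavior-specific and validated by the coaching
    # engine; the log layer only requires a non-empty mapping.
    EventType.GOAL_SET: {},
    EventType.DIARY_ENTRY: {},
    EventType.CONTINUE_CHOICE: {"continue": bool},
    EventType.FOLLOWUP_RESPONSE: {"answer": str},
    EventType.NON_START_REASON: {"reason": str},
    EventType.STUDY_END: {},
}

_GLOBAL_TYPES = {EventType.QUESTIONNAIRE_RESPONSE, EventType.STUDY_END}


def _validate_payload(event_type: EventType, behavior: str, payload: dict, lineno: int) -> None:
    schema = _SCHEMAS[event_type]
    for field, typ in schema.items():
        if field not in payload:
            raise EventLogError(lineno, f"{event_type.value} missing payload field {field!r}")
        if typ is int and isinstance(payload[field], bool):
            raise EventLogError(lineno, f"field {field!r} must be an integer")
        if not isinstance(payload[field], typ):  # type: ignore[arg-type]
            raise EventLogError(lineno, f"field {field!r} has wrong type")
    if event_type is EventType.FOLLOWUP_RESPONSE:
        if payload["answer"] not in {a.value for a in FollowupAnswer}:
            raise EventLogError(lineno, f"unknown follow-up answer {payload['answer']!r}")
    if event_type is EventType.NON_START_REASON:
        if payload["reason"] not in NON_START_REASONS:
            raise EventLogError(lineno, f"unknown non-start reason {payload['reason']!r}")
    if event_type is EventType.DIARY_ENTRY and behavior == BehaviorId.PHYSICAL_ACTIVITY.value:
        band = payload.get("minutes_band")
        if band not in _BAND_NAMES:
            raise EventLogError(lineno, f"unknown minutes band {band!r}")
        if payload.get("effort") not in _EFFORTS:
            raise EventLogError(lineno, f"unknown effort rating {payload.get('effort')!r}")


def parse_event(obj: dict, lineno: int = 0) -> JourneyEvent:
    """Validate one decoded record and build a :class:`JourneyEvent`."""
    for field in ("patient_id", "date", "behavior", "type"):
        if field not in obj:
            raise EventLogError(lineno, f"missing field {field!r}")
    try:
        date = dt.date.fromisoformat(obj["date"])
    except (TypeError, ValueError) as exc:
        raise EventLogError(lineno, f"bad date {obj['date']!r}: {exc}") from None
    try:
        event_type = EventType(obj["type"])
    except ValueError:
        raise EventLogError(lineno, f"unknown event type {obj['type']!r}") from None
    behavior = obj["behavior"]
    if event_type in _GLOBAL_TYPES:
        if behavior != "global":
            raise EventLogError(lineno, f"{event_type.value} must use behavior 'global'")
    elif behavior not in {b.value for b in BehaviorId}:
        raise EventLogError(lineno, f"unknown behavior {behavior!r}")
    payload = obj.get("payload", {})
    if not isinstance(payload, dict):
        raise EventLogError(lineno, "payload must be a mapping")
    _validate_payload(event_type, behavior, payload, lineno)
    if not isinstance(obj["patient_id"], str) or not obj["patient_id"]:
        raise EventLogError(lineno, "patient_id must be a non-empty string")
    return JourneyEvent(obj["patient_id"], date, behavior, event_type, payload)


def read_event_log(source: str | Path | IO[str]) -> list[JourneyEvent]:
    """Read and validate a JSONL event log.

    Raises :class:`EventLogError` (with the offending line number) on a
    malformed line or on out-of-order timestamps within a patient.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            return read_event_log(fh)
    events: list[JourneyEvent] = []
    last_date: dict[str, dt.date] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise EventLogError(lineno, f"invalid JSON: {exc}") from None
        if not isinstance(obj, dict):
            raise EventLogError(lineno, "record must be a JSON object")
        event = parse_event(obj, lineno)
        prev = last_date.get(event.patient_id)
        if prev is not None and event.date < prev:
            raise EventLogError(
                lineno,
                f"out-of-order timestamp for patient {event.patient_id}: "
                f"{event.date} after {prev}",
            )
        last_date[event.patient_id] = event.date
        events.append(event)
    return events


def event_to_json(event: JourneyEvent) -> str:
    """Serialize one event with canonical field order (byte-stable)."""
    record = {
        "patient_id": event.patient_id,
        "date": event.date.isoformat(),
        "behavior": event.behavior,
        "type": event.type.value,
        "payload": {k: event.payload[k] for k in sorted(event.payload)},
    }
    return json.dumps(record, separators=(",", ":"), sort_keys=False)


def write_event_log(events: Iterable[JourneyEvent], dest: str | Path | IO[str]) -> None:
    """Write events as JSONL; identical input yields byte-identical output."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_event_log(events, fh)
        return
    for event in events:
        dest.write(event_to_json(event))
        dest.write("\n")


def dumps_event_log(events: Iterable[JourneyEvent]) -> str:
    buf = io.StringIO()
    write_event_log(events, buf)
    return buf.getvalue()


def iter_patients(events: Iterable[JourneyEvent]) -> Iterator[tuple[str, list[JourneyEvent]]]:
    """Group a validated stream by patient, preserving within-patient order."""
    by_patient: dict[str, list[JourneyEvent]] = {}
    for event in events:
        by_patient.setdefault(event.patient_id, []).append(event)
    for patient_id in by_patient:
        ordered = by_patient[patient_id]
        for a, b in zip(ordered, ordered[1:]):
            if b.date < a.date:
                raise ValidationError(
                    f"events for patient {patient_id} are not timestamp-ordered"
                )
        yield patient_id, ordered
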