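"""Generic event records.

Everything the engine emits or consumes — scheduled actions, patient
responses, vital samples, alerts, proposals, reviews — travels as a flat
`Event` so a whole run can be written to / replayed from a JSONL log.
"""
from __future__ import annotations

import json
from datetime import date, datetime, time
from typing import Any, Iterable

from pydantic import BaseModel, ConfigDict, Field


def _jsonable(x: Any) -> Any:
    if isinstance(x, (datetime, date, time)):
        return x.isoformat()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, BaseModel):
        return _jsonable(x.model_dump())
    return x


class Event(BaseModel):
    """One line of the event log.

    ``seq`` is a per-patient emission counter used only to make ordering (and
    therefore serialized logs) fully deterministic.
    """

    model_config = ConfigDict(frozen=True)

    type: str
    patient_id: str
    date: date
    at: datetime | None = None
    parameter: str | None = None
    payload: dict[str, Any] = Field(default_factory=dict)
    seq: int = 0

    def to_record(self) -> dict[str, Any]:
        return {
            "type": self.type,
            "patient_id": self.patient_id,
            "date": self.date.isoformat(),
            "at": self.at.isoformat() if self.at else None,
            "parameter": self.parameter,
            "payload": _jsonable(self.payload),
            "seq": self.seq,
        }


def events_to_jsonl(events: Iterable[Event]) -> str:
    """Serialize events one-per-line with sorted keys (byte-stable for a fixed stream)."""
    return "".join(json.dumps(e.to_record(), sort_keys=True) + "\n" for e in events)


def events_from_jsonl(text: str) -> list[Event]:
    out: list[Event] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        rec = json.loads(line)
        out.append(Event(**rec))
    return out


def sort_events(events: Iterable[Event]) -> list[Event]:
    """Canonical full ordering: by calendar date, then patient, then emission order."""
    return sorted(events, key=lambda e: (e.date, e.patient_id, e.seq))
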