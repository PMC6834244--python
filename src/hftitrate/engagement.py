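"""Scheduled-action lifecycle and adherence accounting.

Every daily patient obligation (confirm a medication intake, take a vital
measurement, complete a questionnaire) is a :class:`ScheduledAction` with a
5-hour window: it opens one hour before the ideal time and closes four hours
after. A reminder fires 2 hours after the ideal time if the action is still
open; when the window closes unresolved a *no-registration* tag is recorded
and the technical call center phones the patient within 12 hours (shifted to
the next working interval if that falls outside working hours).

Each action ends in exactly one terminal :class:`LedgerEntry`; the ledger is
the unit of account for adherence: adherent = confirmed via the app or
confirmed over the phone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calendars import WorkCalendar
from .errors import ContractViolationError
from .events import Event
from .utils import percent

WINDOW_BEFORE = timedelta(hours=1)
REMINDER_AFTER = timedelta(hours=2)
WINDOW_AFTER = timedelta(hours=4)
CALL_DUE_WITHIN = timedelta(hours=12)


class ActionKind(str, Enum):
    medication_intake = "medication_intake"
    vital_measurement = "vital_measurement"
    questionnaire = "questionnaire"


class Drug(str, Enum):
    beta_blocker = "beta_blocker"
    ace_i = "ace_i"
    diuretic = "diuretic"


class Outcome(str, Enum):
    confirmed_app = "confirmed_app"
    confirmed_callcenter = "confirmed_callcenter"
    declined_app = "declined_app"
    declined_callcenter = "declined_callcenter"
    no_recording = "no_recording"


ADHERENT_OUTCOMES = (Outcome.confirmed_app, Outcome.confirmed_callcenter)


class CallReason(str, Enum):
    missed_vitals = "missed_vitals"
    missed_medication = "missed_medication"
    missed_questionnaire = "missed_questionnaire"
    technical = "technical"


_KIND_TO_REASON = {
    ActionKind.medication_intake: CallReason.missed_medication,
    ActionKind.vital_measurement: CallReason.missed_vitals,
    ActionKind.questionnaire: CallReason.missed_questionnaire,
}


class ScheduledAction(BaseModel):
    """One required patient action; window boundaries derive from ``ideal_time``."""

    model_config = ConfigDict(frozen=True)

    action_id: str
    patient_id: str
    kind: ActionKind
    drug: Drug | None = None
    ideal_time: datetime

    @model_validator(mode="after")
    def _check_drug(self) -> "ScheduledAction":
        if self.kind is ActionKind.medication_intake and self.drug is None:
            raise ValueError("medication_intake actions must name a drug")
        if self.kind is not ActionKind.medication_intake and self.drug is not None:
            raise ValueError("only medication_intake actions carry a drug")
        return self

    @property
    def window_open(self) -> datetime:
        return self.ideal_time - WINDOW_BEFORE

    @property
    def reminder_at(self) -> datetime:
        return self.ideal_time + REMINDER_AFTER

    @property
    def window_close(self) -> datetime:
        return self.ideal_time + WINDOW_AFTER


class LedgerEntry(BaseModel):
    """The single terminal outcome of one scheduled action."""

    model_config = ConfigDict(frozen=True)

    action: ScheduledAction
    outcome: Outcome
    resolved_at: datetime

    @model_validator(mode="after")
    def _check(self) -> "LedgerEntry":
        if self.outcome in (Outcome.confirmed_app, Outcome.declined_app):
            if not self.action.window_open <= self.resolved_at <= self.action.window_close:
                raise ValueError("app outcomes must resolve inside the action window")
        if self.outcome is Outcome.no_recording and self.action.kind is ActionKind.medication_intake:
            raise ValueError("no_recording applies only to vitals/questionnaires")
        return self


class CallRecord(BaseModel):
    """One technical-call-center phone contact."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    placed_at: datetime
    reason: CallReason
    related_action: ScheduledAction | None = None


class Channel(str, Enum):
    app = "app"
    callcenter = "callcenter"


class Answer(str, Enum):
    confirm = "confirm"
    decline = "decline"
    no_response = "no_response"


class PatientResponse(BaseModel):
    """A timestamped patient reaction, via the app or during a phone call."""

    model_config = ConfigDict(frozen=True)

    at: datetime
    channel: Channel
    answer: Answer


@dataclass
class LifecycleResult:
    entry: LedgerEntry
    events: list[Event]
    call: CallRecord | None


def lifecycle(
    action: ScheduledAction,
    patient_events: Sequence[PatientResponse],
    calendar: WorkCalendar | None = None,
) -> LifecycleResult:
    """Resolve one scheduled action to its terminal ledger entry.

    The first in-window app response wins (duplicates ignored); responses
    outside the window never produce an in-window outcome. An unresolved
    window emits reminder and no-registration events and escalates to a
    phone call placed at the first working instant at or after the window
    close (so a Saturday-morning miss is called on Monday). The call resolves
    the entry from the call-channel response; with no usable answer,
    vitals/questionnaires end as ``no_recording`` while medication ends as
    ``declined_callcenter`` (intake could not be confirmed).
    """
    calendar = calendar or WorkCalendar()
    if any(patient_events[i].at > patient_events[i + 1].at for i in range(len(patient_events) - 1)):
        raise ContractViolationError("patient_events must be time-ordered")

    events: list[Event] = []

    def _ev(type_: str, at: datetime, **payload: object) -> None:
        events.append(
            Event(
                type=type_,
                patient_id=action.patient_id,
                date=at.date(),
                at=at,
                payload={"action_id": action.action_id, **payload},
            )
        )

    in_window = [
        r
        for r in patient_events
        if r.channel is Channel.app
        and r.answer in (Answer.confirm, Answer.decline)
        and action.window_open <= r.at <= action.window_close
    ]
    if in_window:
        first = in_window[0]
        if first.at > action.reminder_at:
            _ev("reminder", action.reminder_at)
        outcome = Outcome.confirmed_app if first.answer is Answer.confirm else Outcome.declined_app
        entry = LedgerEntry(action=action, outcome=outcome, resolved_at=first.at)
        return LifecycleResult(entry=entry, events=events, call=None)

    # unresolved at window close: reminder, no-registration tag, call-center escalation
    _ev("reminder", action.reminder_at)
    _ev("no_registration", action.window_close, kind=action.kind.value)

    call_response = next(
        (r for r in patient_events if r.channel is Channel.callcenter and r.at >= action.window_close),
        None,
    )
    due = call_response.at if call_response is not None else action.window_close
    placed_at = calendar.next_working_instant(due)
    reason = _KIND_TO_REASON[action.kind]
    call = CallRecord(
        patient_id=action.patient_id, placed_at=placed_at, reason=reason, related_action=action
    )
    _ev("call_placed", placed_at, reason=reason.value)

    answer = call_response.answer if call_response is not None else Answer.no_response
    if answer is Answer.confirm:
        outcome = Outcome.confirmed_callcenter
    elif answer is Answer.decline:
        outcome = Outcome.declined_callcenter
    elif action.kind is ActionKind.medication_intake:
        outcome = Outcome.declined_callcenter
    else:
        outcome = Outcome.no_recording
    entry = LedgerEntry(action=action, outcome=outcome, resolved_at=placed_at)
    return LifecycleResult(entry=entry, events=events, call=call)


@dataclass
class StratumReport:
    """Outcome counts and percentages for one slice of the ledger."""

    total: int
    counts: dict[str, int]
    percents: dict[str, float]
    adherence_percent: float

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "outcomes": {
                o: {"count": self.counts[o], "percent": self.percents[o]} for o in self.counts
            },
            "adherence_percent": self.adherence_percent,
        }


@dataclass
class AdherenceReport:
    overall: StratumReport
    by_kind: dict[str, StratumReport] = field(default_factory=dict)
    by_drug: dict[str, StratumReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.to_dict(),
            "by_kind": {k: v.to_dict() for k, v in self.by_kind.items()},
            "by_drug": {k: v.to_dict() for k, v in self.by_drug.items()},
        }


def _stratum(entries: Sequence[LedgerEntry]) -> StratumReport:
    counts = {o.value: 0 for o in Outcome}
    for e in entries:
        counts[e.outcome.value] += 1
    counts = {k: v for k, v in counts.items() if v}
    total = len(entries)
    adherent = sum(counts.get(o.value, 0) for o in ADHERENT_OUTCOMES)
    return StratumReport(
        total=total,
        counts=counts,
        percents={k: percent(v, total, 2) for k, v in counts.items()},
        adherence_percent=percent(adherent, total, 2),
    )


def compute_adherence(ledger: Sequence[LedgerEntry]) -> AdherenceReport:
    """Adherence % = (confirmed via app + confirmed via call center) / total.

    Reported overall, per action kind and per drug; percentages at 2 decimals,
    half-up. An empty ledger yields an all-zero report.
    """
    report = AdherenceReport(overall=_stratum(ledger))
    for kind in ActionKind:
        sel = [e for e in ledger if e.action.kind is kind]
        if sel:
            report.by_kind[kind.value] = _stratum(sel)
    for drug in Drug:
        sel = [e for e in ledger if e.action.drug is drug]
        if sel:
            report.by_drug[drug.value] = _stratum(sel)
    return report


@dataclass
class CallStats:
    total: int
    by_reason: dict[str, int]
    per_patient_median: float | None
    per_patient_iqr: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "by_reason": self.by_reason,
            "per_patient_median": self.per_patient_median,
            "per_patient_iqr": list(self.per_patient_iqr) if self.per_patient_iqr else None,
        }


def call_center_stats(calls: Iterable[CallRecord]) -> CallStats:
    """Total calls, per-reason counts, and the per-patient median and IQR.

    Quartiles use linear interpolation, so e.g. per-patient counts [2, 4, 6]
    give median 4 with IQR (3, 5).
    """
    calls = list(calls)
    by_reason: dict[str, int] = {}
    per_patient: dict[str, int] = {}
    for c in calls:
        by_reason[c.reason.value] = by_reason.get(c.reason.value, 0) + 1
        per_patient[c.patient_id] = per_patient.get(c.patient_id, 0) + 1
    if not per_patient:
        return CallStats(total=0, by_reason={}, per_patient_median=None, per_patient_iqr=None)
    counts = np.array(sorted(per_patient.values()), dtype=float)
    q1, med, q3 = np.percentile(counts, [25, 50, 75], method="linear")
    return CallStats(
        total=len(calls),
        by_reason=dict(sorted(by_reason.items())),
        per_patient_median=float(med),
        per_patient_iqr=(float(q1), float(q3)),
    )


def adherence_from_counts(counts: Mapping[Outcome | str, int]) -> float:
    """Adherence percentage straight from outcome counts (2 dp, half-up)."""
    norm = {Outcome(k) if not isinstance(k, Outcome) else k: v for k, v in counts.items()}
    total = sum(norm.values())
    adherent = sum(v for k, v in norm.items() if k in ADHERENT_OUTCOMES)
    return percent(adherent, total, 2)
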