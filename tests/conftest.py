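"""Shared fixtures: compact builders for samples, actions and ledgers."""
from __future__ import annotations

from datetime import date, datetime, time, timedelta

import pytest

from hftitrate.engagement import (
    ActionKind,
    Drug,
    LedgerEntry,
    Outcome,
    ScheduledAction,
)
from hftitrate.telemetry import Source, VitalSample

MONDAY = date(2024, 1, 1)  # anchor; 2024-01-01 is a Monday


def make_sample(
    pid: str = "P1",
    on: date = MONDAY,
    **vitals: float,
) -> VitalSample:
    return VitalSample(
        patient_id=pid,
        date=on,
        source=Source.device_auto,
        recorded_at=datetime.combine(on, time(8, 0)),
        **vitals,
    )


def make_action(
    pid: str = "P1",
    kind: ActionKind = ActionKind.medication_intake,
    drug: Drug | None = Drug.beta_blocker,
    ideal: datetime | None = None,
    action_id: str = "a1",
) -> ScheduledAction:
    if kind is not ActionKind.medication_intake:
        drug = None
    return ScheduledAction(
        action_id=action_id,
        patient_id=pid,
        kind=kind,
        drug=drug,
        ideal_time=ideal or datetime.combine(MONDAY, time(8, 0)),
    )


def entries_from_counts(
    counts: dict[Outcome, int],
    kind: ActionKind = ActionKind.medication_intake,
    drug: Drug | None = Drug.beta_blocker,
) -> list[LedgerEntry]:
    """Expand outcome counts into concrete ledger entries (one shared action
    template per stratum; the accounting only reads kind/drug/outcome)."""
    action = make_action(kind=kind, drug=drug)
    entries: list[LedgerEntry] = []
    for outcome, n in counts.items():
        resolved = (
            action.ideal_time
            if outcome in (Outcome.confirmed_app, Outcome.declined_app)
            else action.window_close + timedelta(hours=1)
        )
        entries.extend(
            LedgerEntry(action=action, outcome=outcome, resolved_at=resolved) for _ in range(n)
        )
    return entries


@pytest.fixture(scope="session")
def medication_ledger() -> list[LedgerEntry]:
    """Medication ledger whose per-drug and per-channel counts reproduce the
    historical accounting: 10,825 intakes, 10,018 confirmed (8,315 in-app,
    1,703 by phone), per-drug confirmed 3,239/3,335 beta-blocker,
    3,549/3,740 ACE-I and 3,230/3,750 diuretic."""
    per_drug = {
        Drug.beta_blocker: {
            Outcome.confirmed_app: 2539,
            Outcome.confirmed_callcenter: 700,
            Outcome.declined_app: 46,
            Outcome.declined_callcenter: 50,
        },
        Drug.ace_i: {
            Outcome.confirmed_app: 2849,
            Outcome.confirmed_callcenter: 700,
            Outcome.declined_app: 91,
            Outcome.declined_callcenter: 100,
        },
        Drug.diuretic: {
            Outcome.confirmed_app: 2927,
            Outcome.confirmed_callcenter: 303,
            Outcome.declined_app: 214,
            Outcome.declined_callcenter: 306,
        },
    }
    entries: list[LedgerEntry] = []
    for drug, counts in per_drug.items():
        entries.extend(entries_from_counts(counts, ActionKind.medication_intake, drug))
    return entries


@pytest.fixture(scope="session")
def vitals_ledger() -> list[LedgerEntry]:
    """Vital-sign ledger: 4,758 scheduled measurements, 3,902 transmitted
    automatically, 602 recovered by phone, 254 never recorded."""
    return entries_from_counts(
        {
            Outcome.confirmed_app: 3902,
            Outcome.confirmed_callcenter: 602,
            Outcome.no_recording: 254,
        },
        ActionKind.vital_measurement,
        drug=None,
    )
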