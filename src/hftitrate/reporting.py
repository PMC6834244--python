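"""End-to-end run reports.

A report is a pure function of the event log: the same JSONL log always
yields byte-identical JSON. It mirrors the study-style summary tables —
proposal-outcome frequencies, nurse-response frequencies (0 decimal places),
the adherence ledger (2 decimal places) and technical-call-center
statistics — plus per-patient titration trajectories.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

from .calendars import WorkCalendar
from .engagement import (
    ActionKind,
    AdherenceReport,
    Answer,
    CallRecord,
    CallStats,
    Channel,
    Drug,
    LedgerEntry,
    PatientResponse,
    ScheduledAction,
    call_center_stats,
    compute_adherence,
    lifecycle,
)
from .events import Event
from .simulate import SimConfig, simulate_cohort
from .titration import CONCLUSIVE_OUTCOMES, ProposalOutcome
from .utils import percent, tabulate


def _parse_dt(v: str | datetime) -> datetime:
    return v if isinstance(v, datetime) else datetime.fromisoformat(v)


def extract_actions(
    events: Sequence[Event],
) -> list[tuple[ScheduledAction, list[PatientResponse]]]:
    """Rebuild scheduled actions and their time-ordered responses from a log."""
    actions: dict[str, ScheduledAction] = {}
    responses: dict[str, list[PatientResponse]] = {}
    for e in events:
        if e.type == "action":
            p = e.payload
            act = ScheduledAction(
                action_id=p["action_id"],
                patient_id=e.patient_id,
                kind=ActionKind(p["kind"]),
                drug=Drug(p["drug"]) if p.get("drug") else None,
                ideal_time=_parse_dt(p["ideal_time"]),
            )
            actions[act.action_id] = act
            responses.setdefault(act.action_id, [])
        elif e.type == "response":
            p = e.payload
            responses.setdefault(p["action_id"], []).append(
                PatientResponse(
                    at=_parse_dt(e.at) if e.at else _parse_dt(p["at"]),
                    channel=Channel(p["channel"]),
                    answer=Answer(p["answer"]),
                )
            )
    out = []
    for aid, act in actions.items():
        out.append((act, sorted(responses.get(aid, []), key=lambda r: r.at)))
    return out


def build_ledger(
    events: Sequence[Event], calendar: WorkCalendar | None = None
) -> tuple[list[LedgerEntry], list[Event], list[CallRecord]]:
    """Pipe every scheduled action in the log through the engagement lifecycle."""
    calendar = calendar or WorkCalendar()
    entries: list[LedgerEntry] = []
    emitted: list[Event] = []
    calls: list[CallRecord] = []
    for act, resps in extract_actions(events):
        res = lifecycle(act, resps, calendar)
        entries.append(res.entry)
        emitted.extend(res.events)
        if res.call is not None:
            calls.append(res.call)
    return entries, emitted, calls


@dataclass
class RunReport:
    adherence: AdherenceReport
    proposals_total: int
    proposals: dict[str, dict[str, float]]
    conclusive_percent: float
    nurse_actions: dict[str, dict[str, float]]
    calls: CallStats
    titration: dict[str, dict[str, dict]]
    phase: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "adherence": self.adherence.to_dict(),
            "proposals": {
                "total": self.proposals_total,
                "by_outcome": self.proposals,
                "conclusive_percent": self.conclusive_percent,
            },
            "nurse_actions": self.nurse_actions,
            "calls": self.calls.to_dict(),
            "titration": self.titration,
            "phase": self.phase,
        }

    def to_json(self) -> str:
        """Deterministic serialization (sorted keys) for idempotent reports."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


def _titration_summary(events: Sequence[Event]) -> dict[str, dict[str, dict]]:
    out: dict[str, dict[str, dict]] = {}
    ladders: dict[tuple[str, str], dict] = {}
    steps: dict[tuple[str, str], int] = {}
    for e in events:
        if e.type == "enrollment":
            for dc, lad in e.payload["ladders"].items():
                ladders[(e.patient_id, dc)] = lad
                steps[(e.patient_id, dc)] = e.payload["initial_steps"][dc]
        elif e.type == "plan_change":
            key = (e.patient_id, e.payload["drug_class"])
            steps[key] = e.payload["new_step_index"]
    for (pid, dc), step in sorted(steps.items()):
        lad = ladders[(pid, dc)]
        out.setdefault(pid, {})[dc] = {
            "drug_name": lad["drug_name"],
            "final_step_index": step,
            "final_dose_mg": lad["steps"][step],
            "max_daily_mg": lad["max_daily"],
            "at_max": step == len(lad["steps"]) - 1,
        }
    return out


def build_report(events: Sequence[Event], calendar: WorkCalendar | None = None) -> RunReport:
    """Aggregate one event log into a full run report (pure, idempotent)."""
    entries, _, calls = build_ledger(events, calendar)

    proposal_counts = {o.value: 0 for o in ProposalOutcome}
    n_proposals = 0
    nurse_counts: dict[str, int] = {}
    n_reviews = 0
    phase: dict = {}
    for e in events:
        if e.type == "proposal":
            proposal_counts[e.payload["outcome"]] += 1
            n_proposals += 1
        elif e.type == "review":
            nurse_counts[e.payload["action"]] = nurse_counts.get(e.payload["action"], 0) + 1
            n_reviews += 1
        elif e.type == "enrollment" and not phase:
            phase = {
                "enrollment_date": e.date.isoformat(),
                "active_phase_days": e.payload["active_phase_days"],
            }
    proposal_counts = {k: v for k, v in proposal_counts.items() if v}
    conclusive = sum(proposal_counts.get(o.value, 0) for o in CONCLUSIVE_OUTCOMES)

    return RunReport(
        adherence=compute_adherence(entries),
        proposals_total=n_proposals,
        proposals=tabulate(proposal_counts, n_proposals, dp=0),
        conclusive_percent=percent(conclusive, n_proposals, 0),
        nurse_actions=tabulate(dict(sorted(nurse_counts.items())), n_reviews, dp=0),
        calls=call_center_stats(calls),
        titration=_titration_summary(events),
        phase=phase,
    )


def summarize_titration(
    events: Sequence[Event], census_days: Iterable[int] = (91, 182)
) -> dict[str, dict[int, dict]]:
    """Share of patients at the guideline maximum dose per drug class on each
    census day (counted from each patient's enrollment).

    A patient counts as *at max* on a census day when the step reached by that
    day is the ladder top; a change applied afterwards counts only at later
    censuses.
    """
    enroll: dict[str, date] = {}
    ladders: dict[tuple[str, str], int] = {}
    initial: dict[tuple[str, str], int] = {}
    changes: dict[tuple[str, str], list[tuple[date, int]]] = {}
    for e in events:
        if e.type == "enrollment":
            enroll[e.patient_id] = e.date
            for dc, lad in e.payload["ladders"].items():
                ladders[(e.patient_id, dc)] = len(lad["steps"]) - 1
                initial[(e.patient_id, dc)] = e.payload["initial_steps"][dc]
        elif e.type == "plan_change":
            key = (e.patient_id, e.payload["drug_class"])
            changes.setdefault(key, []).append((e.date, e.payload["new_step_index"]))

    out: dict[str, dict[int, dict]] = {}
    classes = sorted({dc for (_, dc) in ladders})
    for dc in classes:
        out[dc] = {}
        pids = sorted(pid for (pid, c) in ladders if c == dc)
        for day in census_days:
            n_at_max = 0
            for pid in pids:
                census_date = enroll[pid] + timedelta(days=day)
                step = initial[(pid, dc)]
                for d, s in sorted(changes.get((pid, dc), [])):
                    if d <= census_date:
                        step = s
                n_at_max += step == ladders[(pid, dc)]
            out[dc][day] = {
                "n_at_max": n_at_max,
                "n": len(pids),
                "percent": percent(n_at_max, len(pids), 0),
            }
    return out


@dataclass
class RunResult:
    events: list[Event]
    report: RunReport
    ledger: list[LedgerEntry]
    ground_truth: dict


def run(config: SimConfig) -> RunResult:
    """Simulate a cohort and report on it; deterministic given the seed."""
    cohort = simulate_cohort(config)
    report = build_report(cohort.events, config.calendar)
    entries, _, _ = build_ledger(cohort.events, config.calendar)
    return RunResult(
        events=cohort.events, report=report, ledger=entries, ground_truth=cohort.ground_truth
    )
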