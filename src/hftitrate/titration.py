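"""Semiautomatic medication uptitration engine.

During a ~3-month *active phase* the engine generates a dose-increase
proposal every two weeks, alternating between the β-blocker and the ACE
inhibitor (β-blocker first, at the end of week 2). A short symptom
questionnaire is pushed before every proposal and a kidney-function blood
draw is requested one week before each ACE-I proposal.

Each proposal is classified by a fixed rule cascade into one of five
outcomes: uptitrate, no uptitration (already at the guideline maximum), or
nurse evaluation required — for incomplete data, aberrant vital signs, or
aberrant blood values. The cascade is deliberately conservative: any active
threshold crossing or reported symptom routes the decision to the heart-
failure nurse, so by construction the engine never autonomously proposes a
dose increase in the presence of aberrant data. Every proposal is then
reviewed by the nurse; only a review can change the medication plan, and a
hard safety cap forbids ever stepping past the guideline maximum daily dose.

Diuretics are monitored for adherence only and are never titrated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from enum import Enum
from typing import Literal, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engagement import Drug
from .errors import ConfigurationError, ContractViolationError, SafetyViolationError
from .events import Event
from .telemetry import (
    DEFAULT_THRESHOLDS,
    Crossing,
    SustainedAlert,
    ThresholdSet,
    VitalSample,
    evaluate_sample,
)

PROPOSAL_TIME = time(8, 0)  # proposals are generated at 08:00 local on the due date

#: Guideline maximum daily doses (mg) for the supported agents.
GUIDELINE_MAX_DAILY = {
    "perindopril": 10.0,
    "enalapril": 10.0,
    "ramipril": 10.0,
    "lisinopril": 20.0,
    "candesartan": 16.0,
    "losartan": 100.0,
    "bisoprolol": 10.0,
    "nebivolol": 5.0,
}


class DoseLadder(BaseModel):
    """Ordered permitted daily doses for one agent, ending at the guideline max."""

    model_config = ConfigDict(frozen=True)

    drug_name: str
    drug_class: Literal[Drug.beta_blocker, Drug.ace_i]
    steps: tuple[float, ...]
    max_daily: float = Field(gt=0, description="mg")

    @model_validator(mode="after")
    def _check(self) -> "DoseLadder":
        if not self.steps:
            raise ValueError("ladder needs at least one step")
        if any(a >= b for a, b in zip(self.steps, self.steps[1:])):
            raise ValueError("steps must be strictly increasing")
        if self.steps[-1] != self.max_daily:
            raise ValueError("last step must equal max_daily")
        known = GUIDELINE_MAX_DAILY.get(self.drug_name.lower())
        if known is not None and known != self.max_daily:
            raise ValueError(
                f"{self.drug_name}: max_daily {self.max_daily} differs from guideline {known}"
            )
        return self

    @property
    def top_index(self) -> int:
        return len(self.steps) - 1


def _ladder(name: str, drug_class: Drug, steps: Sequence[float]) -> DoseLadder:
    return DoseLadder(
        drug_name=name, drug_class=drug_class, steps=tuple(steps), max_daily=steps[-1]
    )


#: Common titration ladders; the intermediate steps follow usual heart-failure
#: titration practice, the end points are the guideline maxima.
DEFAULT_LADDERS: dict[str, DoseLadder] = {
    l.drug_name: l
    for l in (
        _ladder("bisoprolol", Drug.beta_blocker, [1.25, 2.5, 3.75, 5.0, 7.5, 10.0]),
        _ladder("nebivolol", Drug.beta_blocker, [1.25, 2.5, 5.0]),
        _ladder("enalapril", Drug.ace_i, [2.5, 5.0, 10.0]),
        _ladder("ramipril", Drug.ace_i, [1.25, 2.5, 5.0, 10.0]),
        _ladder("perindopril", Drug.ace_i, [2.5, 5.0, 10.0]),
        _ladder("lisinopril", Drug.ace_i, [2.5, 5.0, 10.0, 20.0]),
        _ladder("candesartan", Drug.ace_i, [4.0, 8.0, 16.0]),
        _ladder("losartan", Drug.ace_i, [25.0, 50.0, 100.0]),
    )
}


class PlanEntry(BaseModel):
    ladder: DoseLadder
    current_step_index: int = Field(default=0, ge=0)
    at_optimal: bool = False

    @model_validator(mode="after")
    def _check(self) -> "PlanEntry":
        if self.current_step_index > self.ladder.top_index:
            raise ValueError("current_step_index beyond ladder top")
        return self

    @property
    def current_dose(self) -> float:
        return self.ladder.steps[self.current_step_index]

    @property
    def at_top(self) -> bool:
        return self.current_step_index == self.ladder.top_index


class MedicationPlan(BaseModel):
    """A patient's position on each titratable ladder, plus the monitored diuretic."""

    patient_id: str
    entries: dict[Drug, PlanEntry] = Field(default_factory=dict)
    diuretic_dose: float | None = Field(
        default=None, description="mg/day; adherence-monitored only, never titrated"
    )

    @model_validator(mode="after")
    def _check(self) -> "MedicationPlan":
        if Drug.diuretic in self.entries:
            raise ValueError("diuretics are never titrated by the engine")
        for dc, entry in self.entries.items():
            if entry.ladder.drug_class is not dc:
                raise ValueError(f"ladder {entry.ladder.drug_name} is not a {dc.value}")
        return self


class ProposalOutcome(str, Enum):
    UPTITRATE = "UPTITRATE"
    NO_UPTITRATION = "NO_UPTITRATION"
    NURSE_EVAL_INCOMPLETE = "NURSE_EVAL_INCOMPLETE"
    NURSE_EVAL_ABERRANT_VITALS = "NURSE_EVAL_ABERRANT_VITALS"
    NURSE_EVAL_ABERRANT_BLOOD = "NURSE_EVAL_ABERRANT_BLOOD"


#: Outcomes that need no nurse evaluation.
CONCLUSIVE_OUTCOMES = (ProposalOutcome.UPTITRATE, ProposalOutcome.NO_UPTITRATION)


class ProposalEvent(BaseModel):
    """A scheduled (or manual) proposal slot with its prerequisites."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    due_date: date
    drug_class: Literal[Drug.beta_blocker, Drug.ace_i]
    sequence_index: int = Field(ge=0, description="1-based position; 0 for manual slots")
    questionnaire_due_date: date
    blood_request_date: date | None = None

    @model_validator(mode="after")
    def _check(self) -> "ProposalEvent":
        if self.blood_request_date is not None and self.drug_class is not Drug.ace_i:
            raise ValueError("blood requests precede ACE-I proposals only")
        return self

    @property
    def due_at(self) -> datetime:
        return datetime.combine(self.due_date, PROPOSAL_TIME)


class BloodResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: date
    egfr: float = Field(gt=0, description="mL/min/1.73 m^2")
    creatinine: float | None = Field(default=None, gt=0, description="mg/dL")


SYMPTOM_FLAGS = ("dizziness", "dyspnea_worsening", "edema", "fatigue", "other_red_flag")


class SymptomReport(BaseModel):
    """Short pre-proposal questionnaire: generic red-flag booleans + free text."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: date
    flags: dict[str, bool] = Field(default_factory=lambda: {f: False for f in SYMPTOM_FLAGS})
    free_text: str = ""

    @property
    def any_flag(self) -> bool:
        return any(self.flags.values())


@dataclass(frozen=True)
class DataQuality:
    """Assessment of the 14-day evidence window before a proposal."""

    completeness: float
    aberrant: bool
    crossings: tuple[Crossing, ...]


class Evidence(BaseModel):
    """Snapshot the outcome was computed from; stored with the proposal."""

    model_config = ConfigDict(frozen=True)

    completeness: float
    crossings: tuple[Crossing, ...] = ()
    blood: BloodResult | None = None
    symptoms: SymptomReport | None = None


class Proposal(BaseModel):
    model_config = ConfigDict(frozen=True)

    event: ProposalEvent
    outcome: ProposalOutcome
    evidence: Evidence

    @model_validator(mode="after")
    def _check(self) -> "Proposal":
        if (
            self.outcome is ProposalOutcome.NURSE_EVAL_ABERRANT_BLOOD
            and self.event.drug_class is not Drug.ace_i
        ):
            raise ValueError("aberrant-blood outcomes only arise for ACE-I proposals")
        return self


class NurseActionKind(str, Enum):
    CONFIRM = "CONFIRM"
    CONTACT_PATIENT_THEN_DECIDE = "CONTACT_PATIENT_THEN_DECIDE"
    CHANGE_OTHER_MEDICATION = "CHANGE_OTHER_MEDICATION"
    LEAVE_UNCHANGED = "LEAVE_UNCHANGED"
    OPTIMAL_REACHED = "OPTIMAL_REACHED"


class NurseAction(BaseModel):
    model_config = ConfigDict(frozen=True)

    action: NurseActionKind
    final_decision: Literal["uptitrate", "hold"] | None = None
    note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "NurseAction":
        if self.action is NurseActionKind.CONTACT_PATIENT_THEN_DECIDE and self.final_decision is None:
            raise ValueError("contacting the patient must end in a final decision")
        return self


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def build_schedule(
    enrollment_date: date,
    active_phase_days: int = 91,
    interval_days: int = 14,
    first_offset_days: int = 14,
    blood_lead_days: int = 7,
) -> list[ProposalEvent]:
    """Biweekly alternating proposal slots for one patient's active phase.

    Slots fall at enrollment + 14, 28, ... days, alternating β-blocker first;
    floor(active_phase_days / interval_days) slots in total, so the default
    91-day phase yields 6. Each ACE-I slot carries a blood-withdrawal request
    ``blood_lead_days`` before it; every slot carries a pre-proposal
    questionnaire due the day before. After the active phase no slots are
    generated — monitoring continues but proposals stop.
    """
    if active_phase_days < interval_days:
        raise ConfigurationError("active phase must cover at least one interval")
    events: list[ProposalEvent] = []
    n = active_phase_days // interval_days
    for k in range(1, n + 1):
        due = enrollment_date + timedelta(days=first_offset_days + (k - 1) * interval_days)
        drug_class = Drug.beta_blocker if k % 2 == 1 else Drug.ace_i
        events.append(
            ProposalEvent(
                patient_id="",
                due_date=due,
                drug_class=drug_class,
                sequence_index=k,
                questionnaire_due_date=due - timedelta(days=1),
                blood_request_date=(
                    due - timedelta(days=blood_lead_days) if drug_class is Drug.ace_i else None
                ),
            )
        )
    return events


def schedule_for_patient(patient_id: str, events: Sequence[ProposalEvent]) -> list[ProposalEvent]:
    return [e.model_copy(update={"patient_id": patient_id}) for e in events]


def manual_proposal_event(
    patient_id: str, due_date: date, drug_class: Drug, blood_lead_days: int = 7
) -> ProposalEvent:
    """Nurse-requested out-of-schedule slot (e.g. during the less-intensive
    phase); never generated automatically."""
    return ProposalEvent(
        patient_id=patient_id,
        due_date=due_date,
        drug_class=drug_class,
        sequence_index=0,
        questionnaire_due_date=due_date - timedelta(days=1),
        blood_request_date=(
            due_date - timedelta(days=blood_lead_days) if drug_class is Drug.ace_i else None
        ),
    )


# ---------------------------------------------------------------------------
# evidence-window assessment
# ---------------------------------------------------------------------------

def assess_window(
    samples: Sequence[VitalSample],
    due_date: date,
    baseline_weight: float,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    window_days: int = 14,
    alerts: Sequence[SustainedAlert] = (),
) -> DataQuality:
    """Summarize the ``window_days`` before ``due_date`` (due date excluded).

    Completeness is the fraction of window days with at least one vital
    measured (one measurement set per day expected). The window is aberrant
    when any threshold crossing falls inside it or a sustained alert overlaps
    it.
    """
    if window_days < 1:
        raise ConfigurationError("window_days must be >= 1")
    start = due_date - timedelta(days=window_days)
    in_window = [s for s in samples if start <= s.date < due_date]
    measured_days = {s.date for s in in_window if s.measured_parameters}
    crossings: list[Crossing] = []
    for s in sorted(in_window, key=lambda s: s.date):
        crossings.extend(evaluate_sample(s, baseline_weight, thresholds))
    overlapping = any(a.run_start < due_date and a.run_end >= start for a in alerts)
    return DataQuality(
        completeness=len(measured_days) / window_days,
        aberrant=bool(crossings) or overlapping,
        crossings=tuple(crossings),
    )


# ---------------------------------------------------------------------------
# classification cascade
# ---------------------------------------------------------------------------

def classify_proposal(
    event: ProposalEvent,
    quality: DataQuality,
    blood: BloodResult | None,
    symptoms: SymptomReport | None,
    plan: MedicationPlan,
    egfr_baseline: float | None = None,
    completeness_cutoff: float = 0.8,
    egfr_floor: float = 30.0,
    egfr_drop_fraction: float = 0.25,
    blood_max_age_days: int = 14,
) -> Proposal:
    """Pure rule cascade mapping the evidence snapshot to a proposal outcome.

    First matching branch wins:

    1. already at the ladder top, or flagged optimal -> NO_UPTITRATION
    2. window completeness < cutoff, or questionnaire missing -> NURSE_EVAL_INCOMPLETE
    3. aberrant vitals in the window -> NURSE_EVAL_ABERRANT_VITALS
    4. ACE-I only: blood missing/stale -> NURSE_EVAL_INCOMPLETE;
       eGFR < floor or dropped > 25% from baseline -> NURSE_EVAL_ABERRANT_BLOOD
    5. any reported symptom flag -> NURSE_EVAL_ABERRANT_VITALS
    6. otherwise -> UPTITRATE
    """
    entry = plan.entries.get(event.drug_class)
    if entry is None:
        raise ConfigurationError(f"no ladder configured for {event.drug_class.value}")

    evidence = Evidence(
        completeness=quality.completeness,
        crossings=quality.crossings,
        blood=blood,
        symptoms=symptoms,
    )

    def _done(outcome: ProposalOutcome) -> Proposal:
        return Proposal(event=event, outcome=outcome, evidence=evidence)

    if entry.at_top or entry.at_optimal:
        return _done(ProposalOutcome.NO_UPTITRATION)
    if quality.completeness < completeness_cutoff or symptoms is None:
        return _done(ProposalOutcome.NURSE_EVAL_INCOMPLETE)
    if quality.aberrant:
        return _done(ProposalOutcome.NURSE_EVAL_ABERRANT_VITALS)
    if event.drug_class is Drug.ace_i:
        stale = blood is not None and (event.due_date - blood.date).days > blood_max_age_days
        if blood is None or stale:
            return _done(ProposalOutcome.NURSE_EVAL_INCOMPLETE)
        dropped = (
            egfr_baseline is not None
            and blood.egfr < (1.0 - egfr_drop_fraction) * egfr_baseline
        )
        if blood.egfr < egfr_floor or dropped:
            return _done(ProposalOutcome.NURSE_EVAL_ABERRANT_BLOOD)
    if symptoms.any_flag:
        return _done(ProposalOutcome.NURSE_EVAL_ABERRANT_VITALS)
    return _done(ProposalOutcome.UPTITRATE)


# ---------------------------------------------------------------------------
# nurse review
# ---------------------------------------------------------------------------

class AuditRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    due_date: date
    drug_class: Drug
    proposal_outcome: ProposalOutcome
    nurse_action: NurseActionKind
    final_decision: str | None
    step_before: int
    step_after: int
    note: str = ""


class AuditLog:
    """Append-only review trail; also enforces one review per proposal."""

    def __init__(self) -> None:
        self._records: list[AuditRecord] = []
        self._reviewed: set[tuple[str, date, Drug]] = set()

    def mark_reviewed(self, proposal: Proposal) -> None:
        key = (proposal.event.patient_id, proposal.event.due_date, proposal.event.drug_class)
        if key in self._reviewed:
            raise ContractViolationError(f"proposal already reviewed: {key}")
        self._reviewed.add(key)

    def append(self, record: AuditRecord) -> None:
        self._records.append(record)

    @property
    def records(self) -> tuple[AuditRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)


@dataclass
class ReviewResult:
    plan: MedicationPlan
    record: AuditRecord
    events: list[Event] = field(default_factory=list)


def apply_review(
    proposal: Proposal,
    action: NurseAction,
    plan: MedicationPlan,
    audit: AuditLog | None = None,
) -> ReviewResult:
    """Apply the nurse's decision to the plan; the only way a dose changes.

    A confirmed UPTITRATE (or an explicit final decision to uptitrate) moves
    the drug up exactly one ladder step; attempting to step past the guideline
    maximum raises :class:`SafetyViolationError` and changes nothing.
    OPTIMAL_REACHED permanently freezes further proposals for the drug. Every
    review is appended to the audit log, and an applied change emits a
    pop-up notification the patient must confirm.
    """
    if audit is not None:
        audit.mark_reviewed(proposal)

    dc = proposal.event.drug_class
    entry = plan.entries.get(dc)
    if entry is None:
        raise ConfigurationError(f"no ladder configured for {dc.value}")

    kind = action.action
    if kind is NurseActionKind.CONFIRM:
        if proposal.outcome is ProposalOutcome.UPTITRATE:
            decision = "uptitrate"
        elif proposal.outcome is ProposalOutcome.NO_UPTITRATION:
            decision = "hold"
        elif action.final_decision is None:
            raise ContractViolationError(
                "confirming a nurse-evaluation proposal requires an explicit final decision"
            )
        else:
            decision = action.final_decision
    elif kind is NurseActionKind.CONTACT_PATIENT_THEN_DECIDE:
        decision = action.final_decision  # validator guarantees presence
    elif kind is NurseActionKind.OPTIMAL_REACHED:
        decision = "optimal"
    else:  # CHANGE_OTHER_MEDICATION, LEAVE_UNCHANGED
        decision = action.final_decision or "hold"

    step_before = entry.current_step_index
    events: list[Event] = []
    new_entry = entry

    if decision == "uptitrate":
        if entry.at_top:
            raise SafetyViolationError(
                f"{entry.ladder.drug_name} already at guideline maximum "
                f"{entry.ladder.max_daily} mg"
            )
        new_entry = entry.model_copy(update={"current_step_index": step_before + 1})
        events.append(
            Event(
                type="plan_change",
                patient_id=plan.patient_id,
                date=proposal.event.due_date,
                at=proposal.event.due_at,
                payload={
                    "drug_class": dc.value,
                    "drug_name": entry.ladder.drug_name,
                    "new_step_index": new_entry.current_step_index,
                    "new_dose_mg": new_entry.current_dose,
                },
            )
        )
        events.append(
            Event(
                type="plan_notification",
                patient_id=plan.patient_id,
                date=proposal.event.due_date,
                at=proposal.event.due_at,
                payload={"requires_confirmation": True, "drug_class": dc.value},
            )
        )
    elif decision == "optimal":
        new_entry = entry.model_copy(update={"at_optimal": True})

    new_plan = plan.model_copy(update={"entries": {**plan.entries, dc: new_entry}})
    record = AuditRecord(
        patient_id=plan.patient_id,
        due_date=proposal.event.due_date,
        drug_class=dc,
        proposal_outcome=proposal.outcome,
        nurse_action=kind,
        final_decision=decision,
        step_before=step_before,
        step_after=new_entry.current_step_index,
        note=action.note,
    )
    if audit is not None:
        audit.append(record)
    return ReviewResult(plan=new_plan, record=record, events=events)


# ---------------------------------------------------------------------------
# daily plan push
# ---------------------------------------------------------------------------

class PlanMessage(BaseModel):
    """The medication scheme uploaded to the patient's phone each morning."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: date
    doses_mg: dict[str, float]
    changed_since_yesterday: bool


def daily_plan_push(
    plan: MedicationPlan, on: date, previous: PlanMessage | None = None
) -> PlanMessage:
    """Today's per-drug doses; the changed flag compares against yesterday's
    message (and is False on the first push). The diuretic appears in the
    message but its dose never changes through the engine."""
    doses: dict[str, float] = {
        dc.value: entry.current_dose for dc, entry in sorted(plan.entries.items(), key=lambda kv: kv[0].value)
    }
    if plan.diuretic_dose is not None:
        doses[Drug.diuretic.value] = plan.diuretic_dose
    changed = previous is not None and doses != previous.doses_mg
    return PlanMessage(
        patient_id=plan.patient_id, date=on, doses_mg=doses, changed_since_yesterday=changed
    )
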