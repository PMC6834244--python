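"""Synthetic patient-cohort simulator.

No public dataset accompanies this problem, so every other module is
exercised against cohorts generated here: daily scheduled actions with
configurable adherence probabilities, device technical failures with
phone-call recovery, vital-sign trajectories that respond (linearly and
immediately) to the current dose step, pre-proposal questionnaires, blood
draws, and the closed titration loop itself (a configurable nurse policy
reviews every proposal, so the simulated doses feed back into the simulated
vitals).

Default parameters emulate the feasibility-study conditions: 14 patients
followed 182 days, baseline vitals drawn from truncated normals with heart
rate 73 (13) bpm, systolic 112 (14) and diastolic 75 (12) mm Hg, eGFR
50 (28); behavior probabilities chosen so that in expectation ~77% of
medication actions are confirmed in-app, ~16% by phone, and ~18% of device
transmissions fail (of which ~70% are recovered over the phone).

Determinism: each patient's stream comes from an RNG seeded with
``(seed, patient_index)``, so a fixed config reproduces the event stream
byte-for-byte regardless of patient count or ordering.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, time, timedelta
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calendars import WorkCalendar
from .engagement import (
    ActionKind,
    Answer,
    Channel,
    Drug,
    PatientResponse,
    ScheduledAction,
)
from .errors import ConfigurationError
from .events import Event, sort_events
from .telemetry import (
    AlertDispatcher,
    Crossing,
    Parameter,
    Source,
    ThresholdSet,
    VitalSample,
    detect_sustained,
    evaluate_sample,
)
from .titration import (
    SYMPTOM_FLAGS,
    AuditLog,
    BloodResult,
    DEFAULT_LADDERS,
    MedicationPlan,
    NurseAction,
    NurseActionKind,
    PlanEntry,
    Proposal,
    ProposalOutcome,
    SymptomReport,
    apply_review,
    assess_window,
    build_schedule,
    classify_proposal,
    schedule_for_patient,
)

VITAL_PARAMS = ("weight", "heart_rate", "systolic", "diastolic")


class Behavior(BaseModel):
    """Per-patient engagement probabilities.

    ``p_confirm_call`` and ``p_recover_call`` are conditional on the call
    being placed (i.e. on a missed in-app registration / a failed device
    transmission respectively).
    """

    model_config = ConfigDict(frozen=True)

    p_confirm_app: float = Field(default=0.7681, ge=0, le=1)
    p_decline_app: float = Field(default=0.0324, ge=0, le=1)
    p_confirm_call: float = Field(default=0.7885, ge=0, le=1)
    p_tech_failure: float = Field(default=0.18, ge=0, le=1)
    p_recover_call: float = Field(default=0.7033, ge=0, le=1)
    p_symptom: float = Field(default=0.05, ge=0, le=1)
    p_blood_done: float = Field(default=0.9, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "Behavior":
        if self.p_confirm_app + self.p_decline_app > 1:
            raise ValueError("p_confirm_app + p_decline_app must be <= 1")
        return self


class BaselineSpec(BaseModel):
    """Truncated-normal specification for one baseline parameter."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(ge=0)
    lo: float
    hi: float

    @model_validator(mode="after")
    def _check(self) -> "BaselineSpec":
        if not self.lo < self.hi:
            raise ValueError("lo must be below hi")
        if not self.lo <= self.mean <= self.hi:
            raise ValueError("mean must lie inside the truncation range")
        return self


DEFAULT_BASELINES: dict[str, BaselineSpec] = {
    "weight": BaselineSpec(mean=81.0, sd=14.0, lo=40.0, hi=180.0),
    "heart_rate": BaselineSpec(mean=73.0, sd=13.0, lo=40.0, hi=140.0),
    "systolic": BaselineSpec(mean=112.0, sd=14.0, lo=75.0, hi=200.0),
    "diastolic": BaselineSpec(mean=75.0, sd=12.0, lo=45.0, hi=120.0),
    "egfr": BaselineSpec(mean=50.0, sd=28.0, lo=15.0, hi=130.0),
}

#: Per-ladder-step immediate shifts of the daily vitals (linear in step index).
DEFAULT_DOSE_RESPONSE: dict[Drug, dict[str, float]] = {
    Drug.beta_blocker: {"heart_rate": -2.0, "systolic": -1.5, "diastolic": -1.0},
    Drug.ace_i: {"heart_rate": 0.0, "systolic": -3.0, "diastolic": -2.0},
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "weight": 0.4,
    "heart_rate": 4.0,
    "systolic": 7.0,
    "diastolic": 5.0,
    "egfr": 5.0,
}


class PatientProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    baseline: dict[str, float]
    behavior: Behavior
    dose_response: dict[Drug, dict[str, float]]
    noise_sd: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "PatientProfile":
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")
        return self


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    interval_days: int = Field(default=14, ge=1)
    active_phase_days: int = Field(default=91, ge=14)
    first_offset_days: int = Field(default=14, ge=1)
    blood_lead_days: int = Field(default=7, ge=1)


class SimConfig(BaseModel):
    """Cohort-level simulation parameters; the seed fixes the whole stream."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=14, ge=1)
    n_days: int = Field(default=182, ge=1)
    seed: int = 0
    enrollment_date: date = date(2024, 1, 1)  # a Monday
    calendar: WorkCalendar = WorkCalendar()
    vitals_time: time = time(7, 30)
    medication_times: dict[Drug, time] = Field(
        default_factory=lambda: {
            Drug.beta_blocker: time(8, 0),
            Drug.ace_i: time(20, 0),
            Drug.diuretic: time(8, 0),
        }
    )
    questionnaire_time: time = time(9, 0)
    baselines: dict[str, BaselineSpec] = Field(default_factory=lambda: dict(DEFAULT_BASELINES))
    behavior: Behavior = Behavior()
    dose_response: dict[Drug, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DOSE_RESPONSE.items()}
    )
    noise_sd: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    beta_blocker_drug: str = "bisoprolol"
    ace_i_drug: str = "enalapril"
    diuretic_dose: float | None = 40.0  # e.g. furosemide mg/day, monitored only
    thresholds: ThresholdSet = ThresholdSet()
    schedule: ScheduleConfig = ScheduleConfig()

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in (self.beta_blocker_drug, self.ace_i_drug):
            if name not in DEFAULT_LADDERS:
                raise ConfigurationError(f"unknown drug {name!r}")
        for p in (*VITAL_PARAMS, "egfr"):
            if p not in self.baselines:
                raise ConfigurationError(f"missing baseline spec for {p!r}")
        return self


def patient_rng(config: SimConfig, patient_index: int) -> np.random.Generator:
    """Deterministic per-patient substream derived from (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, patient_index]))


def _truncated_normal(spec: BaselineSpec, rng: np.random.Generator) -> float:
    if spec.sd == 0:
        return spec.mean
    for _ in range(1000):
        v = rng.normal(spec.mean, spec.sd)
        if spec.lo <= v <= spec.hi:
            return float(v)
    raise ConfigurationError("truncation range rejects essentially all draws")


def sample_profile(
    config: SimConfig, rng: np.random.Generator, patient_index: int = 0
) -> PatientProfile:
    """Draw one patient's baselines from the configured truncated normals."""
    baseline = {p: _truncated_normal(config.baselines[p], rng) for p in (*VITAL_PARAMS, "egfr")}
    return PatientProfile(
        patient_id=f"P{patient_index:03d}",
        baseline=baseline,
        behavior=config.behavior,
        dose_response={k: dict(v) for k, v in config.dose_response.items()},
        noise_sd=dict(config.noise_sd),
    )


def default_plan(config: SimConfig, patient_id: str) -> MedicationPlan:
    return MedicationPlan(
        patient_id=patient_id,
        entries={
            Drug.beta_blocker: PlanEntry(ladder=DEFAULT_LADDERS[config.beta_blocker_drug]),
            Drug.ace_i: PlanEntry(ladder=DEFAULT_LADDERS[config.ace_i_drug]),
        },
        diuretic_dose=config.diuretic_dose,
    )


# ---------------------------------------------------------------------------
# one simulated day
# ---------------------------------------------------------------------------

@dataclass
class DayResult:
    vital_action: ScheduledAction
    vital_responses: list[PatientResponse]
    sample: VitalSample | None
    tech_failure: bool
    medication: list[tuple[ScheduledAction, list[PatientResponse]]]
    questionnaire: tuple[ScheduledAction, list[PatientResponse]] | None = None
    symptom_report: SymptomReport | None = None


def _app_response_time(action: ScheduledAction, rng: np.random.Generator) -> datetime:
    # uniform over the 5-hour window
    offset_h = rng.uniform(-1.0, 4.0)
    return action.ideal_time + timedelta(hours=float(offset_h))


def _respond_medication(
    action: ScheduledAction, behavior: Behavior, calendar: WorkCalendar, rng: np.random.Generator
) -> list[PatientResponse]:
    u = rng.random()
    if u < behavior.p_confirm_app:
        return [PatientResponse(at=_app_response_time(action, rng), channel=Channel.app, answer=Answer.confirm)]
    if u < behavior.p_confirm_app + behavior.p_decline_app:
        return [PatientResponse(at=_app_response_time(action, rng), channel=Channel.app, answer=Answer.decline)]
    placed = calendar.next_working_instant(action.window_close)
    answer = Answer.confirm if rng.random() < behavior.p_confirm_call else Answer.decline
    return [PatientResponse(at=placed, channel=Channel.callcenter, answer=answer)]


def simulate_day(
    profile: PatientProfile,
    plan: MedicationPlan,
    on: date,
    config: SimConfig,
    rng: np.random.Generator,
    questionnaire_due: bool = False,
) -> DayResult:
    """One patient-day: vitals (dose-responsive, noisy, possibly withheld by a
    technical failure and possibly recovered by phone), one intake action per
    drug on the plan, and optionally the pre-proposal questionnaire."""
    b = profile.behavior

    # --- vitals -----------------------------------------------------------
    values: dict[str, float] = {}
    for p in VITAL_PARAMS:
        shift = 0.0
        for dc, entry in plan.entries.items():
            shift += entry.current_step_index * profile.dose_response.get(dc, {}).get(p, 0.0)
        v = profile.baseline[p] + shift + rng.normal(0.0, profile.noise_sd[p])
        values[p] = max(float(v), 20.0)  # physiologic floor keeps values positive

    measured_at = datetime.combine(on, config.vitals_time)
    vital_action = ScheduledAction(
        action_id=f"{profile.patient_id}:{on.isoformat()}:vitals",
        patient_id=profile.patient_id,
        kind=ActionKind.vital_measurement,
        ideal_time=measured_at,
    )
    tech_failure = rng.random() < b.p_tech_failure
    recover_draw = rng.random()  # drawn unconditionally to keep the stream aligned
    sample: VitalSample | None
    responses: list[PatientResponse]
    if not tech_failure:
        sample = VitalSample(
            patient_id=profile.patient_id,
            date=on,
            weight=values["weight"],
            systolic=values["systolic"],
            diastolic=values["diastolic"],
            heart_rate=values["heart_rate"],
            source=Source.device_auto,
            recorded_at=measured_at,
        )
        responses = [PatientResponse(at=measured_at, channel=Channel.app, answer=Answer.confirm)]
    else:
        placed = config.calendar.next_working_instant(vital_action.window_close)
        if recover_draw < b.p_recover_call:
            sample = VitalSample(
                patient_id=profile.patient_id,
                date=on,
                weight=values["weight"],
                systolic=values["systolic"],
                diastolic=values["diastolic"],
                heart_rate=values["heart_rate"],
                source=Source.callcenter_phone,
                recorded_at=placed,
            )
            responses = [PatientResponse(at=placed, channel=Channel.callcenter, answer=Answer.confirm)]
        else:
            sample = None
            responses = [PatientResponse(at=placed, channel=Channel.callcenter, answer=Answer.no_response)]

    # --- medication intake ------------------------------------------------
    meds: list[tuple[ScheduledAction, list[PatientResponse]]] = []
    drugs = [Drug.beta_blocker, Drug.ace_i] + ([Drug.diuretic] if plan.diuretic_dose is not None else [])
    for drug in drugs:
        act = ScheduledAction(
            action_id=f"{profile.patient_id}:{on.isoformat()}:med:{drug.value}",
            patient_id=profile.patient_id,
            kind=ActionKind.medication_intake,
            drug=drug,
            ideal_time=datetime.combine(on, config.medication_times[drug]),
        )
        meds.append((act, _respond_medication(act, b, config.calendar, rng)))

    result = DayResult(
        vital_action=vital_action,
        vital_responses=responses,
        sample=sample,
        tech_failure=tech_failure,
        medication=meds,
    )

    # --- pre-proposal questionnaire --------------------------------------
    if questionnaire_due:
        qact = ScheduledAction(
            action_id=f"{profile.patient_id}:{on.isoformat()}:questionnaire",
            patient_id=profile.patient_id,
            kind=ActionKind.questionnaire,
            ideal_time=datetime.combine(on, config.questionnaire_time),
        )
        u = rng.random()
        symptom_draw = rng.random()
        flag_pick = int(rng.integers(0, len(SYMPTOM_FLAGS)))
        completed_at: datetime | None
        if u < b.p_confirm_app:
            qresp = [PatientResponse(at=_app_response_time(qact, rng), channel=Channel.app, answer=Answer.confirm)]
            completed_at = qresp[0].at
        else:
            placed = config.calendar.next_working_instant(qact.window_close)
            if rng.random() < b.p_confirm_call:
                qresp = [PatientResponse(at=placed, channel=Channel.callcenter, answer=Answer.confirm)]
                completed_at = placed
            else:
                qresp = [PatientResponse(at=placed, channel=Channel.callcenter, answer=Answer.no_response)]
                completed_at = None
        result.questionnaire = (qact, qresp)
        if completed_at is not None:
            flags = {f: False for f in SYMPTOM_FLAGS}
            if symptom_draw < b.p_symptom:
                flags[SYMPTOM_FLAGS[flag_pick]] = True
            result.symptom_report = SymptomReport(patient_id=profile.patient_id, date=on, flags=flags)
    return result


# ---------------------------------------------------------------------------
# whole cohort with the closed titration loop
# ---------------------------------------------------------------------------

def default_nurse_policy(proposal: Proposal, plan: MedicationPlan) -> NurseAction:
    """Simulated nurse: confirm conclusive proposals; phone the patient for
    nurse-evaluation outcomes, uptitrating only when nothing aberrant was
    seen, and mark the dose optimal once the ladder top is reached."""
    o = proposal.outcome
    entry = plan.entries[proposal.event.drug_class]
    if o is ProposalOutcome.UPTITRATE:
        return NurseAction(action=NurseActionKind.CONFIRM)
    if o is ProposalOutcome.NO_UPTITRATION:
        if entry.at_top and not entry.at_optimal:
            return NurseAction(action=NurseActionKind.OPTIMAL_REACHED)
        return NurseAction(action=NurseActionKind.LEAVE_UNCHANGED)
    if o is ProposalOutcome.NURSE_EVAL_INCOMPLETE:
        ev = proposal.evidence
        clean = not ev.crossings and (ev.symptoms is None or not ev.symptoms.any_flag)
        decision = "uptitrate" if clean and not entry.at_top else "hold"
        return NurseAction(action=NurseActionKind.CONTACT_PATIENT_THEN_DECIDE, final_decision=decision)
    return NurseAction(action=NurseActionKind.CONTACT_PATIENT_THEN_DECIDE, final_decision="hold")


NursePolicy = Callable[[Proposal, MedicationPlan], NurseAction]


@dataclass
class CohortResult:
    events: list[Event]
    ground_truth: dict
    audit: AuditLog
    plans: dict[str, MedicationPlan]

    def jsonl(self) -> str:
        from .events import events_to_jsonl

        return events_to_jsonl(self.events)


def simulate_cohort(config: SimConfig, nurse_policy: NursePolicy | None = None) -> CohortResult:
    """Generate the full, deterministic event stream for one cohort.

    The stream contains everything downstream modules consume: enrollment
    records, scheduled actions with patient responses, vital samples,
    threshold crossings and sustained alerts (with their dispatched pushes
    and review tasks), blood requests/results, symptom reports, proposals,
    nurse reviews and plan changes. The ground-truth record holds the drawn
    profiles for parameter-recovery tests.
    """
    nurse_policy = nurse_policy or default_nurse_policy
    all_events: list[Event] = []
    profiles: list[PatientProfile] = []
    audit = AuditLog()
    final_plans: dict[str, MedicationPlan] = {}

    base_schedule = build_schedule(
        config.enrollment_date,
        active_phase_days=config.schedule.active_phase_days,
        interval_days=config.schedule.interval_days,
        first_offset_days=config.schedule.first_offset_days,
        blood_lead_days=config.schedule.blood_lead_days,
    )

    for idx in range(config.n_patients):
        rng = patient_rng(config, idx)
        profile = sample_profile(config, rng, patient_index=idx)
        profiles.append(profile)
        pid = profile.patient_id
        plan = default_plan(config, pid)
        schedule = schedule_for_patient(pid, base_schedule)
        by_due = {e.due_date: e for e in schedule}
        q_due_dates = {e.questionnaire_due_date for e in schedule}
        blood_requests = {e.blood_request_date: e for e in schedule if e.blood_request_date}

        seq = 0

        def emit(ev: Event) -> None:
            nonlocal seq
            all_events.append(ev.model_copy(update={"seq": seq}))
            seq += 1

        emit(
            Event(
                type="enrollment",
                patient_id=pid,
                date=config.enrollment_date,
                payload={
                    "baseline": profile.baseline,
                    "active_phase_days": config.schedule.active_phase_days,
                    "ladders": {
                        dc.value: {
                            "drug_name": e.ladder.drug_name,
                            "steps": list(e.ladder.steps),
                            "max_daily": e.ladder.max_daily,
                        }
                        for dc, e in plan.entries.items()
                    },
                    "initial_steps": {dc.value: e.current_step_index for dc, e in plan.entries.items()},
                    "diuretic_dose": plan.diuretic_dose,
                },
            )
        )

        samples: list[VitalSample] = []
        crossings: list[Crossing] = []
        sample_dates: dict[Parameter, set[date]] = {p: set() for p in Parameter}
        latest_blood: BloodResult | None = None
        pending_blood: dict[date, date] = {}  # result date -> draw date
        latest_symptoms: SymptomReport | None = None

        for day_i in range(config.n_days):
            today = config.enrollment_date + timedelta(days=day_i)

            day = simulate_day(
                profile, plan, today, config, rng, questionnaire_due=today in q_due_dates
            )

            emit(
                Event(
                    type="action",
                    patient_id=pid,
                    date=today,
                    at=day.vital_action.ideal_time,
                    payload={
                        "action_id": day.vital_action.action_id,
                        "kind": ActionKind.vital_measurement.value,
                        "drug": None,
                        "ideal_time": day.vital_action.ideal_time,
                    },
                )
            )
            for r in day.vital_responses:
                emit(
                    Event(
                        type="response",
                        patient_id=pid,
                        date=today,
                        at=r.at,
                        payload={
                            "action_id": day.vital_action.action_id,
                            "channel": r.channel.value,
                            "answer": r.answer.value,
                        },
                    )
                )
            if day.sample is not None:
                s = day.sample
                samples.append(s)
                emit(
                    Event(
                        type="vital",
                        patient_id=pid,
                        date=today,
                        at=s.recorded_at,
                        payload={
                            "weight": s.weight,
                            "systolic": s.systolic,
                            "diastolic": s.diastolic,
                            "heart_rate": s.heart_rate,
                            "source": s.source.value,
                            "recorded_at": s.recorded_at,
                        },
                    )
                )
                for p in s.measured_parameters:
                    sample_dates[p].add(today)
                for c in evaluate_sample(s, profile.baseline["weight"], config.thresholds):
                    crossings.append(c)
                    emit(
                        Event(
                            type="crossing",
                            patient_id=pid,
                            date=today,
                            parameter=c.parameter.value,
                            payload={"direction": c.direction.value, "value": c.value},
                        )
                    )

            for act, resps in day.medication:
                emit(
                    Event(
                        type="action",
                        patient_id=pid,
                        date=today,
                        at=act.ideal_time,
                        payload={
                            "action_id": act.action_id,
                            "kind": act.kind.value,
                            "drug": act.drug.value,
                            "ideal_time": act.ideal_time,
                        },
                    )
                )
                for r in resps:
                    emit(
                        Event(
                            type="response",
                            patient_id=pid,
                            date=today,
                            at=r.at,
                            payload={
                                "action_id": act.action_id,
                                "channel": r.channel.value,
                                "answer": r.answer.value,
                            },
                        )
                    )

            if day.questionnaire is not None:
                qact, qresps = day.questionnaire
                emit(
                    Event(
                        type="action",
                        patient_id=pid,
                        date=today,
                        at=qact.ideal_time,
                        payload={
                            "action_id": qact.action_id,
                            "kind": qact.kind.value,
                            "drug": None,
                            "ideal_time": qact.ideal_time,
                        },
                    )
                )
                for r in qresps:
                    emit(
                        Event(
                            type="response",
                            patient_id=pid,
                            date=today,
                            at=r.at,
                            payload={
                                "action_id": qact.action_id,
                                "channel": r.channel.value,
                                "answer": r.answer.value,
                            },
                        )
                    )
            if day.symptom_report is not None:
                latest_symptoms = day.symptom_report
                emit(
                    Event(
                        type="symptom_report",
                        patient_id=pid,
                        date=today,
                        payload={"flags": day.symptom_report.flags},
                    )
                )

            # blood withdrawal prerequisite for ACE-I proposals
            if today in blood_requests:
                emit(
                    Event(
                        type="blood_request",
                        patient_id=pid,
                        date=today,
                        payload={"proposal_due": blood_requests[today].due_date},
                    )
                )
                if rng.random() < profile.behavior.p_blood_done:
                    draw_date = today + timedelta(days=2)  # lab turnaround
                    pending_blood[draw_date] = today
            if today in pending_blood:
                egfr = max(profile.baseline["egfr"] + rng.normal(0.0, profile.noise_sd["egfr"]), 5.0)
                latest_blood = BloodResult(patient_id=pid, date=today, egfr=float(egfr))
                emit(
                    Event(
                        type="blood_result",
                        patient_id=pid,
                        date=today,
                        payload={"egfr": latest_blood.egfr},
                    )
                )

            # proposal slot
            if today in by_due:
                ev = by_due[today]
                quality = assess_window(
                    samples,
                    due_date=today,
                    baseline_weight=profile.baseline["weight"],
                    thresholds=config.thresholds,
                    window_days=config.schedule.interval_days,
                )
                symptoms = (
                    latest_symptoms
                    if latest_symptoms is not None
                    and ev.questionnaire_due_date <= latest_symptoms.date <= today
                    else None
                )
                blood = (
                    latest_blood
                    if latest_blood is not None and latest_blood.date <= today
                    else None
                )
                proposal = classify_proposal(
                    ev,
                    quality,
                    blood if ev.drug_class is Drug.ace_i else None,
                    symptoms,
                    plan,
                    egfr_baseline=profile.baseline["egfr"],
                )
                emit(
                    Event(
                        type="proposal",
                        patient_id=pid,
                        date=today,
                        at=ev.due_at,
                        payload={
                            "sequence_index": ev.sequence_index,
                            "drug_class": ev.drug_class.value,
                            "outcome": proposal.outcome.value,
                            "evidence": {
                                "completeness": quality.completeness,
                                "n_crossings": len(quality.crossings),
                                "egfr": blood.egfr if blood else None,
                                "symptoms_reported": symptoms is not None,
                                "any_symptom_flag": bool(symptoms and symptoms.any_flag),
                            },
                        },
                    )
                )
                action = nurse_policy(proposal, plan)
                review = apply_review(proposal, action, plan, audit=audit)
                plan = review.plan
                emit(
                    Event(
                        type="review",
                        patient_id=pid,
                        date=today,
                        at=ev.due_at,
                        payload={
                            "drug_class": ev.drug_class.value,
                            "action": action.action.value,
                            "final_decision": review.record.final_decision,
                            "step_before": review.record.step_before,
                            "step_after": review.record.step_after,
                        },
                    )
                )
                for e in review.events:
                    emit(e)

        # sustained-alert pass over the whole stay
        dispatcher = AlertDispatcher(config.calendar)
        for alert in detect_sustained(crossings, sample_dates, config.thresholds):
            emit(
                Event(
                    type="sustained_alert",
                    patient_id=pid,
                    date=alert.run_end,
                    parameter=alert.parameter.value,
                    payload={"run_start": alert.run_start, "run_end": alert.run_end},
                )
            )
            for e in dispatcher.dispatch(alert):
                emit(e)

        final_plans[pid] = plan

    ground_truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_days": config.n_days,
        "enrollment_date": config.enrollment_date.isoformat(),
        "profiles": [
            {
                "patient_id": p.patient_id,
                "baseline": p.baseline,
                "behavior": p.behavior.model_dump(),
                "dose_response": {dc.value: dict(v) for dc, v in p.dose_response.items()},
                "noise_sd": p.noise_sd,
            }
            for p in profiles
        ],
    }
    return CohortResult(
        events=sort_events(all_events), ground_truth=ground_truth, audit=audit, plans=final_plans
    )
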