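"""Schedule arithmetic, classification cascade, nurse review, plan pushes."""
from __future__ import annotations

from datetime import date, timedelta

import pytest

from hftitrate.engagement import Drug
from hftitrate.errors import ConfigurationError, ContractViolationError, SafetyViolationError
from hftitrate.titration import (
    DEFAULT_LADDERS,
    AuditLog,
    BloodResult,
    DataQuality,
    DoseLadder,
    Evidence,
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
    daily_plan_push,
    manual_proposal_event,
    schedule_for_patient,
)

from .conftest import MONDAY, make_sample

D0 = MONDAY


def make_plan(bb_step: int = 1, ace_step: int = 0, **kw) -> MedicationPlan:
    return MedicationPlan(
        patient_id="P1",
        entries={
            Drug.beta_blocker: PlanEntry(ladder=DEFAULT_LADDERS["bisoprolol"], current_step_index=bb_step),
            Drug.ace_i: PlanEntry(ladder=DEFAULT_LADDERS["enalapril"], current_step_index=ace_step),
        },
        **kw,
    )


def clean_quality(completeness: float = 1.0) -> DataQuality:
    return DataQuality(completeness=completeness, aberrant=False, crossings=())


def no_symptoms(on: date = D0 + timedelta(days=13)) -> SymptomReport:
    return SymptomReport(patient_id="P1", date=on)


def event_for(drug_class: Drug, due: date = D0 + timedelta(days=14)):
    ev = build_schedule(D0)[0 if drug_class is Drug.beta_blocker else 1]
    return ev.model_copy(update={"patient_id": "P1", "due_date": due})


class TestBuildSchedule:
    def test_default_phase_yields_six_alternating_slots(self):
        events = build_schedule(D0, active_phase_days=91)
        assert [(e.due_date - D0).days for e in events] == [14, 28, 42, 56, 70, 84]
        assert [e.drug_class for e in events] == [
            Drug.beta_blocker, Drug.ace_i, Drug.beta_blocker, Drug.ace_i, Drug.beta_blocker, Drug.ace_i,
        ]
        assert [e.sequence_index for e in events] == [1, 2, 3, 4, 5, 6]

    def test_blood_requests_one_week_before_each_ace_slot(self):
        events = build_schedule(D0, active_phase_days=91)
        blood_days = [(e.blood_request_date - D0).days for e in events if e.blood_request_date]
        assert blood_days == [21, 49, 77]
        assert all(e.blood_request_date is None for e in events if e.drug_class is Drug.beta_blocker)

    def test_questionnaire_precedes_every_slot(self):
        for e in build_schedule(D0):
            assert e.questionnaire_due_date == e.due_date - timedelta(days=1)

    def test_minimal_phase_single_beta_blocker_slot(self):
        events = build_schedule(D0, active_phase_days=14)
        assert len(events) == 1 and events[0].drug_class is Drug.beta_blocker

    @pytest.mark.parametrize("days, expected", [(14, 1), (27, 1), (28, 2), (91, 6), (97, 6), (98, 7)])
    def test_slot_count_is_floor_of_phase_over_interval(self, days, expected):
        assert len(build_schedule(D0, active_phase_days=days)) == expected

    def test_too_short_phase_rejected(self):
        with pytest.raises(ConfigurationError):
            build_schedule(D0, active_phase_days=10)

    def test_patient_binding(self):
        events = schedule_for_patient("P9", build_schedule(D0))
        assert all(e.patient_id == "P9" for e in events)

    def test_manual_slot_hook(self):
        ev = manual_proposal_event("P1", D0 + timedelta(days=120), Drug.ace_i)
        assert ev.sequence_index == 0
        assert ev.blood_request_date == ev.due_date - timedelta(days=7)


class TestAssessWindow:
    def test_complete_clean_window(self):
        due = D0 + timedelta(days=14)
        samples = [make_sample(on=D0 + timedelta(days=i), heart_rate=70) for i in range(14)]
        q = assess_window(samples, due, baseline_weight=80.0)
        assert q.completeness == 1.0 and not q.aberrant

    def test_partial_window_completeness(self):
        due = D0 + timedelta(days=14)
        samples = [make_sample(on=D0 + timedelta(days=i), heart_rate=70) for i in range(10)]
        q = assess_window(samples, due, baseline_weight=80.0)
        assert q.completeness == pytest.approx(10 / 14)

    def test_single_crossing_makes_window_aberrant(self):
        due = D0 + timedelta(days=14)
        samples = [
            make_sample(on=D0 + timedelta(days=i), heart_rate=(55 if i == 5 else 70)) for i in range(14)
        ]
        q = assess_window(samples, due, baseline_weight=80.0)
        assert q.aberrant and len(q.crossings) == 1

    def test_samples_outside_window_ignored(self):
        due = D0 + timedelta(days=14)
        samples = [make_sample(on=due, heart_rate=40), make_sample(on=D0 - timedelta(days=1), heart_rate=40)]
        q = assess_window(samples, due, baseline_weight=80.0)
        assert q.completeness == 0.0 and not q.aberrant


class TestClassifyProposal:
    def test_clean_complete_window_uptitrates(self):
        p = classify_proposal(
            event_for(Drug.beta_blocker), clean_quality(), None, no_symptoms(), make_plan(bb_step=1)
        )
        assert p.outcome is ProposalOutcome.UPTITRATE

    def test_at_guideline_max_proposes_no_uptitration(self):
        plan = make_plan(bb_step=5)  # bisoprolol 10 mg, the guideline max
        p = classify_proposal(event_for(Drug.beta_blocker), clean_quality(), None, no_symptoms(), plan)
        assert p.outcome is ProposalOutcome.NO_UPTITRATION

    def test_at_optimal_flag_freezes(self):
        plan = make_plan()
        entry = plan.entries[Drug.beta_blocker].model_copy(update={"at_optimal": True})
        plan = plan.model_copy(update={"entries": {**plan.entries, Drug.beta_blocker: entry}})
        p = classify_proposal(event_for(Drug.beta_blocker), clean_quality(), None, no_symptoms(), plan)
        assert p.outcome is ProposalOutcome.NO_UPTITRATION

    def test_incomplete_window_routes_to_nurse(self):
        p = classify_proposal(
            event_for(Drug.beta_blocker), clean_quality(0.5), None, no_symptoms(), make_plan()
        )
        assert p.outcome is ProposalOutcome.NURSE_EVAL_INCOMPLETE

    def test_missing_questionnaire_routes_to_nurse(self):
        p = classify_proposal(event_for(Drug.beta_blocker), clean_quality(), None, None, make_plan())
        assert p.outcome is ProposalOutcome.NURSE_EVAL_INCOMPLETE

    def test_aberrant_window_routes_to_nurse(self):
        q = DataQuality(completeness=1.0, aberrant=True, crossings=())
        p = classify_proposal(event_for(Drug.beta_blocker), q, None, no_symptoms(), make_plan())
        assert p.outcome is ProposalOutcome.NURSE_EVAL_ABERRANT_VITALS

    def test_low_egfr_flags_aberrant_blood_before_uptitration(self):
        blood = BloodResult(patient_id="P1", date=D0 + timedelta(days=10), egfr=25.0)
        p = classify_proposal(
            event_for(Drug.ace_i), clean_quality(), blood, no_symptoms(), make_plan(), egfr_baseline=50.0
        )
        assert p.outcome is ProposalOutcome.NURSE_EVAL_ABERRANT_BLOOD

    def test_egfr_drop_over_quarter_flags_aberrant_blood(self):
        blood = BloodResult(patient_id="P1", date=D0 + timedelta(days=10), egfr=40.0)
        p = classify_proposal(
            event_for(Drug.ace_i), clean_quality(), blood, no_symptoms(), make_plan(), egfr_baseline=60.0
        )
        assert p.outcome is ProposalOutcome.NURSE_EVAL_ABERRANT_BLOOD

    def test_missing_or_stale_blood_counts_as_incomplete(self):
        p = classify_proposal(event_for(Drug.ace_i), clean_quality(), None, no_symptoms(), make_plan())
        assert p.outcome is ProposalOutcome.NURSE_EVAL_INCOMPLETE
        stale = BloodResult(patient_id="P1", date=D0 - timedelta(days=10), egfr=70.0)
        p = classify_proposal(event_for(Drug.ace_i), clean_quality(), stale, no_symptoms(), make_plan())
        assert p.outcome is ProposalOutcome.NURSE_EVAL_INCOMPLETE

    def test_fresh_normal_blood_allows_ace_uptitration(self):
        blood = BloodResult(patient_id="P1", date=D0 + timedelta(days=10), egfr=70.0)
        p = classify_proposal(
            event_for(Drug.ace_i), clean_quality(), blood, no_symptoms(), make_plan(), egfr_baseline=72.0
        )
        assert p.outcome is ProposalOutcome.UPTITRATE

    def test_symptom_flag_routes_to_nurse(self):
        symptoms = SymptomReport(
            patient_id="P1", date=D0 + timedelta(days=13), flags={"dizziness": True}
        )
        p = classify_proposal(event_for(Drug.beta_blocker), clean_quality(), None, symptoms, make_plan())
        assert p.outcome is ProposalOutcome.NURSE_EVAL_ABERRANT_VITALS

    def test_top_step_wins_over_other_branches(self):
        """Cascade order: branch 1 fires even with incomplete aberrant data."""
        q = DataQuality(completeness=0.2, aberrant=True, crossings=())
        p = classify_proposal(event_for(Drug.beta_blocker), q, None, None, make_plan(bb_step=5))
        assert p.outcome is ProposalOutcome.NO_UPTITRATION

    def test_pure_function_identical_evidence_identical_outcome(self):
        args = (event_for(Drug.beta_blocker), clean_quality(), None, no_symptoms(), make_plan())
        assert classify_proposal(*args).outcome is classify_proposal(*args).outcome

    def test_unconfigured_drug_class_is_configuration_error(self):
        plan = MedicationPlan(patient_id="P1", entries={})
        with pytest.raises(ConfigurationError):
            classify_proposal(event_for(Drug.beta_blocker), clean_quality(), None, no_symptoms(), plan)


def _proposal(outcome: ProposalOutcome, drug_class=Drug.beta_blocker) -> Proposal:
    return Proposal(
        event=event_for(drug_class),
        outcome=outcome,
        evidence=Evidence(completeness=1.0),
    )


class TestApplyReview:
    def test_confirmed_uptitration_moves_one_ladder_step(self):
        plan = make_plan(bb_step=1)  # bisoprolol 2.5 mg
        res = apply_review(_proposal(ProposalOutcome.UPTITRATE), NurseAction(action=NurseActionKind.CONFIRM), plan)
        assert res.plan.entries[Drug.beta_blocker].current_dose == 3.75
        assert plan.entries[Drug.beta_blocker].current_dose == 2.5  # input untouched
        assert {e.type for e in res.events} == {"plan_change", "plan_notification"}
        assert res.events[1].payload["requires_confirmation"] is True

    def test_contact_then_hold_leaves_plan_unchanged_with_full_audit(self):
        plan = make_plan(bb_step=1)
        audit = AuditLog()
        res = apply_review(
            _proposal(ProposalOutcome.NURSE_EVAL_ABERRANT_VITALS),
            NurseAction(action=NurseActionKind.CONTACT_PATIENT_THEN_DECIDE, final_decision="hold"),
            plan,
            audit=audit,
        )
        assert res.plan.entries[Drug.beta_blocker].current_step_index == 1
        assert len(audit) == 1
        rec = audit.records[0]
        assert rec.nurse_action is NurseActionKind.CONTACT_PATIENT_THEN_DECIDE
        assert rec.final_decision == "hold"

    def test_uptitrating_past_the_top_is_a_safety_violation(self):
        plan = make_plan(bb_step=5)
        with pytest.raises(SafetyViolationError):
            apply_review(_proposal(ProposalOutcome.UPTITRATE), NurseAction(action=NurseActionKind.CONFIRM), plan)

    def test_optimal_reached_freezes_future_proposals(self):
        plan = make_plan(bb_step=3)
        res = apply_review(
            _proposal(ProposalOutcome.NO_UPTITRATION), NurseAction(action=NurseActionKind.OPTIMAL_REACHED), plan
        )
        assert res.plan.entries[Drug.beta_blocker].at_optimal
        p = classify_proposal(event_for(Drug.beta_blocker), clean_quality(), None, no_symptoms(), res.plan)
        assert p.outcome is ProposalOutcome.NO_UPTITRATION

    def test_second_review_of_same_proposal_rejected(self):
        audit = AuditLog()
        plan = make_plan()
        prop = _proposal(ProposalOutcome.UPTITRATE)
        apply_review(prop, NurseAction(action=NurseActionKind.CONFIRM), plan, audit=audit)
        with pytest.raises(ContractViolationError):
            apply_review(prop, NurseAction(action=NurseActionKind.CONFIRM), plan, audit=audit)

    def test_contact_requires_final_decision(self):
        with pytest.raises(ValueError):
            NurseAction(action=NurseActionKind.CONTACT_PATIENT_THEN_DECIDE)

    def test_confirming_nurse_eval_without_decision_rejected(self):
        with pytest.raises(ContractViolationError):
            apply_review(
                _proposal(ProposalOutcome.NURSE_EVAL_INCOMPLETE),
                NurseAction(action=NurseActionKind.CONFIRM),
                make_plan(),
            )


class TestDailyPlanPush:
    def test_unchanged_plan_not_flagged(self):
        plan = make_plan(diuretic_dose=40.0)
        m1 = daily_plan_push(plan, D0)
        m2 = daily_plan_push(plan, D0 + timedelta(days=1), previous=m1)
        assert not m1.changed_since_yesterday and not m2.changed_since_yesterday
        assert m2.doses_mg["diuretic"] == 40.0

    def test_uptitration_flags_next_morning_message(self):
        plan = make_plan()
        m1 = daily_plan_push(plan, D0)
        res = apply_review(_proposal(ProposalOutcome.UPTITRATE), NurseAction(action=NurseActionKind.CONFIRM), plan)
        m2 = daily_plan_push(res.plan, D0 + timedelta(days=1), previous=m1)
        assert m2.changed_since_yesterday

    def test_diuretic_never_changes_through_engine(self):
        plan = make_plan(diuretic_dose=40.0)
        res = apply_review(_proposal(ProposalOutcome.UPTITRATE), NurseAction(action=NurseActionKind.CONFIRM), plan)
        assert res.plan.diuretic_dose == 40.0


class TestDoseLadders:
    def test_guideline_maxima_enforced(self):
        for name, expected in [("bisoprolol", 10), ("enalapril", 10), ("lisinopril", 20), ("losartan", 100)]:
            assert DEFAULT_LADDERS[name].max_daily == expected
        with pytest.raises(ValueError):
            DoseLadder(drug_name="bisoprolol", drug_class=Drug.beta_blocker, steps=(5.0, 15.0), max_daily=15.0)

    def test_steps_strictly_increasing_ending_at_max(self):
        with pytest.raises(ValueError):
            DoseLadder(drug_name="x", drug_class=Drug.ace_i, steps=(5.0, 5.0), max_daily=5.0)
        with pytest.raises(ValueError):
            DoseLadder(drug_name="x", drug_class=Drug.ace_i, steps=(2.5, 5.0), max_daily=10.0)

    def test_diuretic_cannot_enter_plan_entries(self):
        with pytest.raises(ValueError):
            MedicationPlan(
                patient_id="P1",
                entries={Drug.diuretic: PlanEntry(ladder=DEFAULT_LADDERS["bisoprolol"])},
            )
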