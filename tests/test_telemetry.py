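"""Threshold crossing and sustained-alert detection."""
from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hftitrate.errors import ContractViolationError, IdempotencyError, RejectedSampleError
from hftitrate.telemetry import (
    AlertDispatcher,
    Crossing,
    Direction,
    Parameter,
    SustainedAlert,
    ThresholdSet,
    detect_sustained,
    evaluate_sample,
    on_alert,
)

from .conftest import MONDAY, make_sample

BASELINE_W = 80.0


class TestEvaluateSample:
    @pytest.mark.parametrize(
        "vitals, expected",
        [
            # strict low/high bounds for HR and pressures
            ({"heart_rate": 55, "systolic": 120, "diastolic": 75}, [(Parameter.heart_rate, Direction.low)]),
            ({"heart_rate": 101}, [(Parameter.heart_rate, Direction.high)]),
            ({"systolic": 89}, [(Parameter.systolic, Direction.low)]),
            ({"systolic": 161}, [(Parameter.systolic, Direction.high)]),
            ({"diastolic": 59}, [(Parameter.diastolic, Direction.low)]),
            ({"diastolic": 96}, [(Parameter.diastolic, Direction.high)]),
            # boundary values are normal (strict inequalities)
            ({"heart_rate": 60, "systolic": 90, "diastolic": 60}, []),
            ({"heart_rate": 100, "systolic": 160, "diastolic": 95}, []),
            # weight alarm is inclusive at baseline + 2 kg
            ({"weight": 82.0}, [(Parameter.weight, Direction.high)]),
            ({"weight": 81.9}, []),
            # several simultaneous crossings
            (
                {"heart_rate": 55, "systolic": 161, "weight": 85.0},
                [
                    (Parameter.weight, Direction.high),
                    (Parameter.heart_rate, Direction.low),
                    (Parameter.systolic, Direction.high),
                ],
            ),
        ],
    )
    def test_crossing_rules(self, vitals, expected):
        crossings = evaluate_sample(make_sample(**vitals), BASELINE_W)
        assert [(c.parameter, c.direction) for c in crossings] == expected

    def test_weight_switch_point_matches_inclusive_rule(self):
        """Enumerate weights 79.0-83.0 in 0.1 steps against the inclusive rule."""
        for tenth in range(790, 831):
            w = tenth / 10.0
            got = evaluate_sample(make_sample(weight=w), BASELINE_W)
            expect_cross = w >= BASELINE_W + 2.0
            assert bool(got) == expect_cross, w
            if got:
                assert got[0].value == w

    def test_absent_parameters_produce_no_crossing(self):
        assert evaluate_sample(make_sample(weight=70.0), BASELINE_W) == []

    def test_rejects_empty_sample_and_bad_baseline(self):
        with pytest.raises(RejectedSampleError):
            evaluate_sample(make_sample(), BASELINE_W)
        with pytest.raises(ContractViolationError):
            evaluate_sample(make_sample(heart_rate=70), 0.0)

    def test_non_positive_vital_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_sample(heart_rate=-5)

    def test_stateless(self):
        s = make_sample(heart_rate=55)
        assert evaluate_sample(s, BASELINE_W) == evaluate_sample(s, BASELINE_W)


def _hr_crossings(days: list[int], pid: str = "P1") -> list[Crossing]:
    return [
        Crossing(
            patient_id=pid,
            date=MONDAY + timedelta(days=d),
            parameter=Parameter.heart_rate,
            direction=Direction.low,
            value=55,
        )
        for d in days
    ]


class TestDetectSustained:
    def test_three_day_run_alerts_once(self):
        alerts = detect_sustained(_hr_crossings([0, 1, 2]))
        assert alerts == [
            SustainedAlert(
                patient_id="P1",
                parameter=Parameter.heart_rate,
                run_start=MONDAY,
                run_end=MONDAY + timedelta(days=2),
            )
        ]

    def test_gap_breaks_the_run(self):
        # crossed days 0,1 then missing day 2, crossed day 3
        assert detect_sustained(_hr_crossings([0, 1, 3])) == []

    def test_alternating_parameters_never_alert(self):
        crossings = _hr_crossings([0, 2, 4]) + [
            Crossing(
                patient_id="P1",
                date=MONDAY + timedelta(days=d),
                parameter=Parameter.systolic,
                direction=Direction.low,
                value=85,
            )
            for d in (1, 3, 5)
        ]
        crossings.sort(key=lambda c: c.date)
        assert detect_sustained(crossings) == []

    def test_four_day_run_yields_exactly_one_alert(self):
        alerts = detect_sustained(_hr_crossings([0, 1, 2, 3]))
        assert len(alerts) == 1
        a = alerts[0]
        assert (a.run_end - a.run_start).days + 1 == 3  # fires on day 3 of the run

    def test_two_separate_runs_alert_twice(self):
        alerts = detect_sustained(_hr_crossings([0, 1, 2, 4, 5, 6]))
        assert len(alerts) == 2

    def test_contract_checks(self):
        with pytest.raises(ContractViolationError):
            detect_sustained(list(reversed(_hr_crossings([0, 1]))))
        with pytest.raises(ContractViolationError):
            detect_sustained(_hr_crossings([0, 0]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_bruteforce_window_scan(self, days):
        """Alerts equal a brute-force scan over all contiguous 3-day windows,
        with one alert per maximal run."""
        crossings: list[Crossing] = []
        crossed: dict[Parameter, set[date]] = {p: set() for p in Parameter}
        params = [Parameter.weight, Parameter.heart_rate, Parameter.systolic, Parameter.diastolic]
        for i, flags in enumerate(days):
            d = MONDAY + timedelta(days=i)
            for p, f in zip(params, flags):
                if f:
                    crossed[p].add(d)
                    crossings.append(
                        Crossing(patient_id="P1", date=d, parameter=p, direction=Direction.high, value=999)
                    )

        expected = set()
        for p, ds in crossed.items():
            for d in ds:
                run = all(d + timedelta(days=k) in ds for k in range(3))
                maximal_start = d - timedelta(days=1) not in ds
                if run and maximal_start:
                    expected.add((p, d, d + timedelta(days=2)))

        got = {(a.parameter, a.run_start, a.run_end) for a in detect_sustained(crossings)}
        assert got == expected
        # never an alert for a parameter crossed on < 3 days
        for p, ds in crossed.items():
            if len(ds) < 3:
                assert all(a[0] is not p for a in got)


def _alert(run_end_offset: int, parameter=Parameter.heart_rate) -> SustainedAlert:
    end = MONDAY + timedelta(days=run_end_offset)
    return SustainedAlert(
        patient_id="P1", parameter=parameter, run_start=end - timedelta(days=2), run_end=end
    )


class TestOnAlert:
    def test_weekday_run_end_visible_same_day(self):
        events = on_alert(_alert(2))  # Wednesday
        review = next(e for e in events if e.type == "clinical_review_task")
        assert review.payload["visible_on"] == (MONDAY + timedelta(days=2)).isoformat()

    def test_weekend_run_end_deferred_to_monday(self):
        events = on_alert(_alert(5))  # Saturday
        review = next(e for e in events if e.type == "clinical_review_task")
        assert review.payload["visible_on"] == (MONDAY + timedelta(days=7)).isoformat()

    def test_same_day_alerts_share_one_questionnaire_but_not_review_tasks(self):
        d = AlertDispatcher()
        events = d.dispatch(_alert(2)) + d.dispatch(_alert(2, Parameter.systolic))
        assert sum(e.type == "questionnaire_push" for e in events) == 1
        assert sum(e.type == "clinical_review_task" for e in events) == 2

    def test_duplicate_dispatch_raises(self):
        d = AlertDispatcher()
        d.dispatch(_alert(2))
        with pytest.raises(IdempotencyError):
            d.dispatch(_alert(2))


def test_threshold_set_validation():
    with pytest.raises(ValueError):
        ThresholdSet(hr_low=110, hr_high=100)
    with pytest.raises(ValueError):
        ThresholdSet(run_length=0)
    with pytest.raises(ValueError):
        ThresholdSet(weight_gain=-1)
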