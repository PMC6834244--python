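"""Daily vital-sign threshold monitoring.

Remote sensors transmit weight, blood pressure and heart rate once a day.
Each sample is checked against fixed alarm bounds; when the *same* parameter
violates its bound on ``run_length`` (default 3) consecutive calendar days, a
sustained alert fires: the patient receives a symptom questionnaire and the
clinical call center gets a review task (deferred to Monday when the run ends
on a weekend).

Boundary semantics: heart-rate and blood-pressure bounds are strict (a value
must be < low or > high to cross; 60 bpm with a 60 bpm low bound is normal),
while the weight alarm is inclusive at baseline + ``weight_gain`` kg, because
that level is itself the alarm value. The baseline weight is the enrollment
weight stored on the patient profile and is never updated automatically.
"""
from __future__ import annotations

from datetime import date, datetime, timedelta
from enum import Enum
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calendars import WorkCalendar
from .errors import ContractViolationError, IdempotencyError, RejectedSampleError
from .events import Event


class Parameter(str, Enum):
    weight = "weight"
    heart_rate = "heart_rate"
    systolic = "systolic"
    diastolic = "diastolic"


class Direction(str, Enum):
    low = "low"
    high = "high"


class Source(str, Enum):
    device_auto = "device_auto"
    callcenter_phone = "callcenter_phone"


class VitalSample(BaseModel):
    """One day's measurement set for one patient. Absent vitals are ``None``.

    Device-transmitted samples are recorded the moment they are measured, so
    ``recorded_at`` must fall on ``date``. Phone-recovered samples keep the
    measurement date but may be recorded later (the call center works Monday
    to Friday), so the constraint is relaxed to recorded_at >= date.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: date
    weight: float | None = Field(default=None, gt=0, description="kg")
    systolic: float | None = Field(default=None, gt=0, description="mm Hg")
    diastolic: float | None = Field(default=None, gt=0, description="mm Hg")
    heart_rate: float | None = Field(default=None, gt=0, description="bpm")
    source: Source = Source.device_auto
    recorded_at: datetime

    @model_validator(mode="after")
    def _check_dates(self) -> "VitalSample":
        if self.source is Source.device_auto and self.recorded_at.date() != self.date:
            raise ValueError("device samples must be recorded on their measurement date")
        if self.recorded_at.date() < self.date:
            raise ValueError("recorded_at precedes measurement date")
        return self

    def value(self, parameter: Parameter) -> float | None:
        return getattr(self, parameter.value)

    @property
    def measured_parameters(self) -> list[Parameter]:
        return [p for p in Parameter if self.value(p) is not None]


class ThresholdSet(BaseModel):
    """Alarm bounds; all crossings must persist ``run_length`` days to alert."""

    model_config = ConfigDict(frozen=True)

    weight_gain: float = Field(default=2.0, gt=0, description="kg above baseline")
    hr_low: float = 60.0
    hr_high: float = 100.0
    sbp_low: float = 90.0
    sbp_high: float = 160.0
    dbp_low: float = 60.0
    dbp_high: float = 95.0
    run_length: int = Field(default=3, ge=1, description="consecutive days")

    @model_validator(mode="after")
    def _check_bounds(self) -> "ThresholdSet":
        for lo, hi in ((self.hr_low, self.hr_high), (self.sbp_low, self.sbp_high), (self.dbp_low, self.dbp_high)):
            if not lo < hi:
                raise ValueError("low bound must be below high bound")
        return self

    def bounds(self, parameter: Parameter) -> tuple[float | None, float | None]:
        """(low, high) strict bounds; weight has no bounds here (handled inclusively)."""
        return {
            Parameter.heart_rate: (self.hr_low, self.hr_high),
            Parameter.systolic: (self.sbp_low, self.sbp_high),
            Parameter.diastolic: (self.dbp_low, self.dbp_high),
            Parameter.weight: (None, None),
        }[parameter]


class Crossing(BaseModel):
    """A single-day threshold violation. Weight crossings are always ``high``."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: date
    parameter: Parameter
    direction: Direction
    value: float

    @model_validator(mode="after")
    def _check_weight_direction(self) -> "Crossing":
        if self.parameter is Parameter.weight and self.direction is not Direction.high:
            raise ValueError("weight has no low bound; crossings are always high")
        return self


class SustainedAlert(BaseModel):
    """The same parameter crossed on ``run_length`` consecutive measured days.

    One alert per maximal run: ``run_end`` is the day the alert fires
    (run_start + run_length - 1); continued crossing does not re-alert until
    the run is broken by a normal or missing day.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    parameter: Parameter
    run_start: date
    run_end: date


DEFAULT_THRESHOLDS = ThresholdSet()


def evaluate_sample(
    sample: VitalSample,
    baseline_weight: float,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> list[Crossing]:
    """Check one sample against the bounds; stateless, one Crossing per violation.

    Parameters absent from the sample produce no crossing. Raises
    :class:`RejectedSampleError` when the sample carries no vitals at all and
    :class:`ContractViolationError` for a non-positive baseline weight.
    """
    if baseline_weight <= 0:
        raise ContractViolationError("baseline_weight must be positive")
    if not sample.measured_parameters:
        raise RejectedSampleError("sample contains no vital values")

    crossings: list[Crossing] = []

    def _cross(parameter: Parameter, direction: Direction, value: float) -> None:
        crossings.append(
            Crossing(
                patient_id=sample.patient_id,
                date=sample.date,
                parameter=parameter,
                direction=direction,
                value=value,
            )
        )

    if sample.weight is not None and sample.weight >= baseline_weight + thresholds.weight_gain:
        _cross(Parameter.weight, Direction.high, sample.weight)
    for param in (Parameter.heart_rate, Parameter.systolic, Parameter.diastolic):
        v = sample.value(param)
        if v is None:
            continue
        lo, hi = thresholds.bounds(param)
        if v < lo:
            _cross(param, Direction.low, v)
        elif v > hi:
            _cross(param, Direction.high, v)
    return crossings


def detect_sustained(
    crossings: Sequence[Crossing],
    sample_dates: Mapping[Parameter, Iterable[date]] | None = None,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> list[SustainedAlert]:
    """Find runs of the same parameter crossed on consecutive calendar days.

    ``crossings`` must be date-sorted with at most one entry per
    (date, parameter). A day with a normal measurement or with no measurement
    at all breaks the run (a crossing can only exist on a measured day, so
    consecutiveness of crossing dates encodes both break conditions). When
    ``sample_dates`` is given, every crossing date must appear in it for its
    parameter — a cheap consistency check on the caller's bookkeeping.

    Emits exactly one alert per maximal run of length >= ``run_length``, with
    ``run_end = run_start + run_length - 1`` (the day the rule first fires).
    """
    if any(crossings[i].date > crossings[i + 1].date for i in range(len(crossings) - 1)):
        raise ContractViolationError("crossings must be sorted by date")
    seen: set[tuple[date, Parameter]] = set()
    for c in crossings:
        key = (c.date, c.parameter)
        if key in seen:
            raise ContractViolationError(f"duplicate crossing for {key}")
        seen.add(key)
        if sample_dates is not None and c.date not in set(sample_dates.get(c.parameter, ())):
            raise ContractViolationError(f"crossing on unmeasured day {key}")

    run_length = thresholds.run_length
    alerts: list[SustainedAlert] = []
    by_param: dict[Parameter, list[Crossing]] = {}
    for c in crossings:
        by_param.setdefault(c.parameter, []).append(c)

    for param, items in by_param.items():
        dates = [c.date for c in items]
        i = 0
        while i < len(dates):
            j = i
            while j + 1 < len(dates) and dates[j + 1] == dates[j] + timedelta(days=1):
                j += 1
            if j - i + 1 >= run_length:
                alerts.append(
                    SustainedAlert(
                        patient_id=items[i].patient_id,
                        parameter=param,
                        run_start=dates[i],
                        run_end=dates[i] + timedelta(days=run_length - 1),
                    )
                )
            i = j + 1
    alerts.sort(key=lambda a: (a.run_start, a.parameter.value))
    return alerts


class AlertDispatcher:
    """Turns sustained alerts into outbound events, exactly once per alert.

    Two things happen on alert: a symptom questionnaire is pushed to the
    patient (dated the day the run completes) and the clinical call center
    receives a review task. Questionnaire pushes for several alerts of the
    same patient ending the same day are collapsed into one; review tasks are
    not. Review tasks becoming due on a weekend are visible the next working
    day. Re-dispatching the same alert raises :class:`IdempotencyError`.
    """

    def __init__(self, calendar: WorkCalendar | None = None) -> None:
        self.calendar = calendar or WorkCalendar()
        self._dispatched: set[tuple[str, Parameter, date]] = set()
        self._questionnaires: set[tuple[str, date]] = set()

    def dispatch(self, alert: SustainedAlert) -> list[Event]:
        key = (alert.patient_id, alert.parameter, alert.run_start)
        if key in self._dispatched:
            raise IdempotencyError(f"alert already dispatched: {key}")
        self._dispatched.add(key)

        events: list[Event] = []
        qkey = (alert.patient_id, alert.run_end)
        if qkey not in self._questionnaires:
            self._questionnaires.add(qkey)
            events.append(
                Event(
                    type="questionnaire_push",
                    patient_id=alert.patient_id,
                    date=alert.run_end,
                    payload={"trigger": "sustained_alert"},
                )
            )
        visible_on = (
            alert.run_end
            if self.calendar.is_working_day(alert.run_end)
            else self.calendar.next_working_day(alert.run_end)
        )
        events.append(
            Event(
                type="clinical_review_task",
                patient_id=alert.patient_id,
                date=alert.run_end,
                parameter=alert.parameter.value,
                payload={
                    "run_start": alert.run_start.isoformat(),
                    "run_end": alert.run_end.isoformat(),
                    "visible_on": visible_on.isoformat(),
                },
            )
        )
        return events


def on_alert(
    alert: SustainedAlert,
    calendar: WorkCalendar | None = None,
    dispatcher: AlertDispatcher | None = None,
) -> list[Event]:
    """Dispatch one alert. Pass a shared ``dispatcher`` to get de-duplication
    and idempotency across multiple alerts."""
    if dispatcher is None:
        dispatcher = AlertDispatcher(calendar)
    return dispatcher.dispatch(alert)
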