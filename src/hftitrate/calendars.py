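"""Working-hours calendar.

Both the clinical and the technical call center operate only during working
hours; anything that falls due outside them (nights, weekends) is deferred to
the next working instant — notifications arriving over the weekend are read on
Monday morning.
"""
from __future__ import annotations

from datetime import date, datetime, time, timedelta

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class WorkCalendar(BaseModel):
    """Days of week and daily hours during which call-center staff work.

    ``working_days`` uses Python weekday numbering (Monday=0 .. Sunday=6);
    default Monday-Friday, 08:00-17:00.
    """

    model_config = ConfigDict(frozen=True)

    working_days: frozenset[int] = frozenset({0, 1, 2, 3, 4})
    day_start: time = time(8, 0)
    day_end: time = time(17, 0)

    @field_validator("working_days")
    @classmethod
    def _check_days(cls, v: frozenset[int]) -> frozenset[int]:
        if not v:
            raise ValueError("working_days must be non-empty")
        if not all(0 <= d <= 6 for d in v):
            raise ValueError("weekday numbers must be in 0..6")
        return v

    @model_validator(mode="after")
    def _check_hours(self) -> "WorkCalendar":
        if self.day_start >= self.day_end:
            raise ValueError("day_start must precede day_end")
        return self

    def is_working_day(self, d: date) -> bool:
        return d.weekday() in self.working_days

    def is_working_instant(self, t: datetime) -> bool:
        return self.is_working_day(t.date()) and self.day_start <= t.time() < self.day_end

    def next_working_day(self, d: date) -> date:
        """First working day strictly after ``d``."""
        d = d + timedelta(days=1)
        while not self.is_working_day(d):
            d += timedelta(days=1)
        return d

    def next_working_instant(self, t: datetime) -> datetime:
        """``t`` itself if inside working hours, else the next opening instant."""
        if self.is_working_instant(t):
            return t
        d = t.date()
        if self.is_working_day(d) and t.time() < self.day_start:
            return datetime.combine(d, self.day_start)
        return datetime.combine(self.next_working_day(d), self.day_start)
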