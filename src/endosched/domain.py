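"""Shared data model for endoscopy-unit scheduling.

Patients on a waiting list carry the clinical features used to predict
their procedure duration, a priority class with an associated recommended
due date, and (for evaluation only) the actual procedure duration.
Endoscopists provide capacity in per-day working blocks; a schedule is a
set of (patient, endoscopist, day, start-minute) assignments.

Day indexing is integer, with the planning horizon starting at day 1.
Due dates may be negative: a patient can already be overdue when the
horizon opens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Patient",
    "Endoscopist",
    "CapacityCalendar",
    "Assignment",
    "Schedule",
    "MetricsReport",
    "lateness_days",
    "room_day_balance",
    "build_report",
    "validate_schedule",
    "SchedulingError",
    "ConfigurationError",
    "MissingAssignmentError",
    "DegenerateConfigurationError",
    "NoUsableDataError",
    "CapabilityError",
    "InvalidPredictionError",
    "PRIORITIES",
    "PRIORITY_RANK",
    "AGE_BANDS",
    "BMI_BANDS",
    "FAILED_REASONS",
    "PROCEDURE_TYPES",
    "INDICATIONS",
    "ENDOSCOPIST_TYPES",
    "SEXES",
    "BUFFER_MINUTES",
    "FIXED_SLOT_MINUTES",
    "DEFAULT_DAILY_BUDGET",
    "DURATION_BOUNDS",
]


class SchedulingError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(SchedulingError):
    """Invalid user-supplied configuration (bad probabilities, unknown spec...)."""


class MissingAssignmentError(SchedulingError):
    """A patient was expected in a schedule but is not assigned."""


class DegenerateConfigurationError(SchedulingError):
    """A configuration with no usable capacity (zero room-days)."""


class NoUsableDataError(SchedulingError):
    """Data cleaning removed every row."""


class CapabilityError(SchedulingError):
    """A model lacks a capability (e.g. no importance measure)."""


class InvalidPredictionError(SchedulingError):
    """A nonpositive predicted duration reached the appointment rule."""


# Category vocabularies (waiting-list schema).
SEXES = ("M", "F")
AGE_BANDS = ("<45", "45-59", "60-80", ">80")
BMI_BANDS = ("<25", "25-30", ">30", "missing")
PRIORITIES = ("P2", "P3", "P4", "P5", "SURV")
PRIORITY_RANK = {p: i for i, p in enumerate(PRIORITIES)}  # lower rank = more urgent
FAILED_REASONS = ("poor preparation", "technical difficulties",
                  "disease-related", "other", "none")
PROCEDURE_TYPES = ("colonoscopy", "gastroscopy", "other")
INDICATIONS = ("high", "intermediate", "low", "surveillance")
ENDOSCOPIST_TYPES = ("gastrointestinal", "colorectal", "hepatologic", "thoracic")

#: Minutes added to a predicted procedure time for consent, preparation and
#: transfer in and out of the room — the planned appointment length.
BUFFER_MINUTES = 15.0
#: Flat appointment length of the current-practice baseline.
FIXED_SLOT_MINUTES = 30.0
#: Daily operational time budget per room (minutes, breaks excluded).
DEFAULT_DAILY_BUDGET = 390.0
#: Plausible range of a single procedure in minutes; durations outside it
#: are treated as recording errors.
DURATION_BOUNDS = (2.0, 85.0)


@dataclass
class Patient:
    """One waiting-list entry.

    ``actual_procedure_minutes`` is ground truth used only when evaluating a
    schedule; planning sees ``predicted_procedure_minutes`` (or nothing, in
    fixed-slot mode) via ``appointment_minutes``.
    """

    id: str
    sex: str
    age_band: str
    bmi_band: str
    priority: str
    comorbidity_score: int
    respiratory: bool
    cardiovascular: bool
    diabetes: bool
    prior_pelvic_surgery: bool
    past_failed_colonoscopy: bool
    failed_reason: str
    procedure_type: str
    indication: str
    endoscopist_type: str
    admission_date: int
    due_date: int
    designated_endoscopist: Optional[str] = None
    actual_procedure_minutes: Optional[float] = None
    predicted_procedure_minutes: Optional[float] = None
    appointment_minutes: Optional[float] = None

    def __post_init__(self) -> None:
        if self.admission_date > self.due_date:
            raise ConfigurationError(
                f"patient {self.id}: admission date {self.admission_date} "
                f"after due date {self.due_date}")
        if (self.failed_reason == "none") == bool(self.past_failed_colonoscopy):
            raise ConfigurationError(
                f"patient {self.id}: failed_reason={self.failed_reason!r} "
                f"inconsistent with past_failed_colonoscopy="
                f"{self.past_failed_colonoscopy}")


@dataclass(frozen=True)
class Endoscopist:
    id: str
    specialty: str
    accepts_non_nominative: bool
    compatible_procedures: frozenset

    def __post_init__(self) -> None:
        if not self.compatible_procedures:
            raise ConfigurationError(
                f"endoscopist {self.id}: empty compatible_procedures")

    def can_perform(self, procedure_type: str) -> bool:
        return procedure_type in self.compatible_procedures


class CapacityCalendar:
    """Working-block minutes per (endoscopist, day); missing pairs mean 0."""

    def __init__(self, days: Sequence[int],
                 block_minutes: Mapping[tuple, float]) -> None:
        self.days = list(days)
        self.block_minutes = {}
        for (eid, day), minutes in block_minutes.items():
            if minutes < 0:
                raise ConfigurationError(
                    f"negative block minutes for ({eid}, {day})")
            self.block_minutes[(eid, int(day))] = float(minutes)

    def minutes(self, endoscopist_id: str, day: int) -> float:
        return self.block_minutes.get((endoscopist_id, day), 0.0)

    def room_days(self) -> Iterable[tuple]:
        """(endoscopist_id, day) pairs with positive capacity, in day order."""
        return sorted(self.block_minutes, key=lambda k: (k[1], k[0]))

    @property
    def n_room_days(self) -> int:
        return sum(1 for m in self.block_minutes.values() if m > 0)

    @property
    def total_capacity(self) -> float:
        return float(sum(self.block_minutes.values()))


@dataclass(frozen=True)
class Assignment:
    patient_id: str
    endoscopist_id: str
    day: int
    start_minute: float
    planned_minutes: float


class Schedule:
    """A set of planned appointments produced by one policy."""

    def __init__(self, assignments: Iterable[Assignment],
                 policy_label: str = "") -> None:
        self.assignments = list(assignments)
        self.policy_label = policy_label
        self._by_patient = {}
        for a in self.assignments:
            if a.patient_id in self._by_patient:
                raise ConfigurationError(
                    f"patient {a.patient_id} assigned more than once")
            self._by_patient[a.patient_id] = a

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._by_patient

    def assignment_for(self, patient_id: str) -> Assignment:
        try:
            return self._by_patient[patient_id]
        except KeyError:
            raise MissingAssignmentError(
                f"patient {patient_id} is not scheduled") from None

    def on_room_day(self, endoscopist_id: str, day: int) -> list:
        return [a for a in self.assignments
                if a.endoscopist_id == endoscopist_id and a.day == day]


def lateness_days(schedule: Schedule, patient: Patient) -> int:
    """Overdue days of a scheduled patient: max(0, scheduled day - due date)."""
    a = schedule.assignment_for(patient.id)
    return max(0, a.day - patient.due_date)


def _actual_appointment_minutes(patient: Patient,
                                buffer_minutes: float = BUFFER_MINUTES) -> float:
    if patient.actual_procedure_minutes is None:
        raise ConfigurationError(
            f"patient {patient.id} has no actual duration; cannot evaluate")
    return patient.actual_procedure_minutes + buffer_minutes


def room_day_balance(schedule: Schedule, patients: Mapping[str, Patient],
                     endoscopist_id: str, day: int, budget_minutes: float,
                     buffer_minutes: float = BUFFER_MINUTES) -> tuple:
    """(overtime, earliness) of one room-day against its time budget.

    Evaluation is on realized time: each appointment consumes its *actual*
    procedure duration plus the buffer, regardless of what was planned.
    At most one of the two components is positive.
    """
    if budget_minutes <= 0:
        raise ConfigurationError("budget_minutes must be positive")
    s = sum(_actual_appointment_minutes(patients[a.patient_id], buffer_minutes)
            for a in schedule.on_room_day(endoscopist_id, day))
    return max(0.0, s - budget_minutes), max(0.0, budget_minutes - s)


@dataclass
class MetricsReport:
    """Per-policy throughput, lateness, waiting, overtime and earliness.

    ``avg_late_days`` averages over scheduled patients only (unscheduled
    patients have no scheduled day; they are counted in ``n_unscheduled``).
    ``avg_wait_days`` is scheduled day minus admission date, an alternative
    delay metric measured from list entry rather than from the due date.
    Per-room-day averages divide totals by n_days x n_rooms.
    """

    policy: str
    n_scheduled_total: int
    n_unscheduled: int
    n_scheduled_by_class: dict
    avg_late_days_total: float
    avg_late_days_by_class: dict
    avg_wait_days_total: float
    avg_wait_days_by_class: dict
    total_overtime_minutes: float
    avg_overtime_per_day_room: float
    total_earliness_minutes: float
    avg_earliness_per_day_room: float
    n_room_days: int

    def to_row(self) -> dict:
        row = {
            "policy": self.policy,
            "n_scheduled": self.n_scheduled_total,
            "n_unscheduled": self.n_unscheduled,
            "avg_late_days": self.avg_late_days_total,
            "avg_wait_days": self.avg_wait_days_total,
            "total_overtime_min": self.total_overtime_minutes,
            "avg_overtime_min_per_day_room": self.avg_overtime_per_day_room,
            "total_earliness_min": self.total_earliness_minutes,
            "avg_earliness_min_per_day_room": self.avg_earliness_per_day_room,
        }
        for cls in PRIORITIES:
            row[f"n_{cls}"] = self.n_scheduled_by_class.get(cls, 0)
            row[f"avg_late_{cls}"] = self.avg_late_days_by_class.get(
                cls, float("nan"))
        return row


def build_report(schedule: Schedule, cohort: Sequence[Patient],
                 calendar: CapacityCalendar, budget_minutes: float,
                 buffer_minutes: float = BUFFER_MINUTES) -> MetricsReport:
    """Aggregate lateness over scheduled patients and overtime/earliness
    over every room-day of the calendar."""
    room_days = list(calendar.room_days())
    if not room_days:
        raise DegenerateConfigurationError("calendar has zero room-days")
    by_id = {p.id: p for p in cohort}

    counts: dict = {c: 0 for c in PRIORITIES}
    late_sums: dict = {c: 0.0 for c in PRIORITIES}
    wait_sums: dict = {c: 0.0 for c in PRIORITIES}
    n_sched = 0
    for p in cohort:
        if p.id not in schedule:
            continue
        n_sched += 1
        a = schedule.assignment_for(p.id)
        counts[p.priority] += 1
        late_sums[p.priority] += max(0, a.day - p.due_date)
        wait_sums[p.priority] += a.day - p.admission_date

    total_ot = total_early = 0.0
    for eid, day in room_days:
        ot, early = room_day_balance(schedule, by_id, eid, day,
                                     budget_minutes, buffer_minutes)
        total_ot += ot
        total_early += early

    n_rd = len(room_days)

    def _avg(sums: dict, ns: dict) -> dict:
        return {c: (sums[c] / ns[c]) if ns[c] else float("nan")
                for c in PRIORITIES}

    total_late = sum(late_sums.values())
    total_wait = sum(wait_sums.values())
    return MetricsReport(
        policy=schedule.policy_label,
        n_scheduled_total=n_sched,
        n_unscheduled=len(cohort) - n_sched,
        n_scheduled_by_class=dict(counts),
        avg_late_days_total=total_late / n_sched if n_sched else float("nan"),
        avg_late_days_by_class=_avg(late_sums, counts),
        avg_wait_days_total=total_wait / n_sched if n_sched else float("nan"),
        avg_wait_days_by_class=_avg(wait_sums, counts),
        total_overtime_minutes=total_ot,
        avg_overtime_per_day_room=total_ot / n_rd,
        total_earliness_minutes=total_early,
        avg_earliness_per_day_room=total_early / n_rd,
        n_room_days=n_rd,
    )


def validate_schedule(schedule: Schedule, cohort: Sequence[Patient],
                      endoscopists: Sequence[Endoscopist],
                      calendar: CapacityCalendar,
                      enforce_capacity: bool = True) -> None:
    """Assert the structural invariants of a schedule; raise on violation.

    Checks compatibility (assigned endoscopist can perform the procedure and
    honours nomination), at-most-one appointment per patient (by Schedule
    construction), per-room-day capacity on planned minutes, and that planned
    intra-day appointments of one endoscopist do not overlap.
    """
    by_pid = {p.id: p for p in cohort}
    by_eid = {e.id: e for e in endoscopists}
    for a in schedule.assignments:
        p = by_pid[a.patient_id]
        e = by_eid[a.endoscopist_id]
        if not e.can_perform(p.procedure_type):
            raise SchedulingError(
                f"{e.id} cannot perform {p.procedure_type} (patient {p.id})")
        if p.designated_endoscopist is not None \
                and a.endoscopist_id != p.designated_endoscopist:
            raise SchedulingError(
                f"nominative patient {p.id} assigned to {a.endoscopist_id}, "
                f"not {p.designated_endoscopist}")
        if a.day not in calendar.days:
            raise SchedulingError(f"assignment on day {a.day} outside horizon")
    for eid, day in calendar.room_days():
        apps = sorted(schedule.on_room_day(eid, day),
                      key=lambda a: a.start_minute)
        planned = sum(a.planned_minutes for a in apps)
        cap = calendar.minutes(eid, day)
        if enforce_capacity and planned > cap + 1e-6:
            raise SchedulingError(
                f"room-day ({eid}, {day}): planned {planned} exceeds {cap}")
        for prev, nxt in zip(apps, apps[1:]):
            if prev.start_minute + prev.planned_minutes > nxt.start_minute + 1e-6:
                raise SchedulingError(
                    f"overlap on ({eid}, {day}) between {prev.patient_id} "
                    f"and {nxt.patient_id}")
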