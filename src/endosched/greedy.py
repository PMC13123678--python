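"""Greedy waiting-list scheduler.

Patients are sorted into a single global waiting list by (1) descending
priority, (2) ascending due date, (3) descending planned appointment
length, then taken in order. A nominative patient goes to the earliest
feasible opening of their designated endoscopist; a non-nominative patient
goes to the earliest feasible day over all accepting, compatible
endoscopists, choosing among same-day candidates the one with the most
remaining minutes (roster order breaks ties). Appointments are packed
back-to-back within a day; with flat 30-minute slots this reduces to the
classic 30-minute grid. A patient who fits nowhere is left unscheduled and
the scan continues down the list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .domain import (PRIORITY_RANK, Assignment, CapacityCalendar,
                     ConfigurationError, Endoscopist, Patient, Schedule)
from .duration import appointment_duration

__all__ = ["SortedWaitlist", "sort_waiting_list", "schedule_greedy"]


@dataclass
class SortedWaitlist:
    patients: list
    sort_keys: dict  # patient id -> the tuple it was ordered by
    mode: str


def _sort_key(p: Patient) -> tuple:
    # Final tie-break: admission date ascending, then id, for determinism.
    return (PRIORITY_RANK[p.priority], p.due_date, -p.appointment_minutes,
            p.admission_date, p.id)


def sort_waiting_list(cohort: Sequence[Patient], mode: str) -> SortedWaitlist:
    """Fill planned appointment lengths for ``mode`` and sort the list."""
    for p in cohort:
        p.appointment_minutes = appointment_duration(
            p.predicted_procedure_minutes, mode)
    ordered = sorted(cohort, key=_sort_key)
    return SortedWaitlist(ordered, {p.id: _sort_key(p) for p in ordered}, mode)


def schedule_greedy(waitlist: SortedWaitlist,
                    endoscopists: Sequence[Endoscopist],
                    calendar: CapacityCalendar,
                    mode: str | None = None) -> Schedule:
    """Assign patients in waiting-list order to the earliest feasible slot."""
    mode = mode or waitlist.mode
    by_eid = {e.id: e for e in endoscopists}
    remaining = {(e.id, d): calendar.minutes(e.id, d)
                 for e in endoscopists for d in calendar.days}
    accepting = [e for e in endoscopists if e.accepts_non_nominative]
    roster_order = {e.id: i for i, e in enumerate(endoscopists)}
    if not accepting and any(p.designated_endoscopist is None
                             for p in waitlist.patients):
        warnings.warn("no endoscopist accepts non-nominative patients; "
                      "those patients will stay unscheduled")

    assignments = []
    for p in waitlist.patients:
        need = p.appointment_minutes
        if need is None or need <= 0:
            raise ConfigurationError(
                f"patient {p.id} has no planned appointment length")
        if p.designated_endoscopist is not None:
            if p.designated_endoscopist not in by_eid:
                raise ConfigurationError(
                    f"unknown designated endoscopist "
                    f"{p.designated_endoscopist} (patient {p.id})")
            candidates = [by_eid[p.designated_endoscopist]]
        else:
            candidates = [e for e in accepting
                          if e.can_perform(p.procedure_type)]
        best = None  # (day, -remaining, roster order, eid)
        for e in candidates:
            for d in calendar.days:
                if remaining[(e.id, d)] + 1e-9 >= need:
                    key = (d, -remaining[(e.id, d)], roster_order[e.id], e.id)
                    if best is None or key < best:
                        best = key
                    break
        if best is None:
            continue  # fits nowhere in the horizon; skip, keep scanning
        day, _, _, eid = best
        start = calendar.minutes(eid, day) - remaining[(eid, day)]
        remaining[(eid, day)] -= need
        assignments.append(Assignment(p.id, eid, day, start, need))
    return Schedule(assignments, policy_label=f"greedy-{mode}")
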