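"""Day-level assignment MIP.

Binary variables x[p, e, d] assign patient p to endoscopist e on day d.
The objective maximizes

    w1 * (number of patients scheduled) - w2 * sum of squared overdue days,

where a patient scheduled on day d > d_p (their due date) contributes
(d - d_p)^2. Squaring the overdue term spreads unavoidable lateness evenly
across patients instead of concentrating it on a few. Constraints: a
patient may only see an endoscopist in their compatible set E_p (the
designated one alone, for nominative patients), the planned minutes per
(endoscopist, day) may not exceed that day's working block, and each
patient gets at most one appointment.

The weights must satisfy w1 > w2 * (max possible overdue days)^2 so that
scheduling a patient, however late, always beats leaving them off the
schedule; ``build_instance`` enforces this, scaling w2 down with a warning
if needed. Because the appointment count dominates, the solver in effect
fills the horizon and only then arbitrates lateness.

Solved exactly by branch-and-bound (HiGHS via ``scipy.optimize.milp``),
with the weights scaled to an integer-valued objective so optimality is
certified quickly. ``brute_force_oracle`` is an independent exhaustive
enumerator for small instances, used to cross-check the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, sparse

from .domain import (Assignment, CapacityCalendar, ConfigurationError,
                     Endoscopist, Patient, Schedule, SchedulingError)
from .greedy import _sort_key

__all__ = ["MipInstance", "MipSolution", "build_instance", "solve",
           "brute_force_oracle", "sequence_within_day", "schedule_mip"]

DEFAULT_W1 = 1.0
DEFAULT_W2 = 1e-3


@dataclass
class MipInstance:
    patient_ids: list
    durations: dict          # patient id -> planned appointment minutes
    due_dates: dict          # patient id -> due day
    eligible: dict           # patient id -> tuple of endoscopist ids (E_p)
    endoscopist_ids: list
    days: list
    capacity: dict           # (endoscopist id, day) -> minutes
    w1: float = DEFAULT_W1
    w2: float = DEFAULT_W2

    @property
    def n_variables(self) -> int:
        return sum(len(self.eligible[p]) for p in self.patient_ids) \
            * len(self.days)

    def max_lateness(self) -> int:
        if not self.days or not self.patient_ids:
            return 0
        last = max(self.days)
        return max(0, max(last - self.due_dates[p] for p in self.patient_ids))

    def penalty(self, pid: str, day: int) -> float:
        return self.w2 * max(0, day - self.due_dates[pid]) ** 2


@dataclass
class MipSolution:
    assignments: list        # (patient id, endoscopist id, day)
    objective: float
    gap: float
    status: str
    instance: MipInstance


def build_instance(cohort: Sequence[Patient],
                   endoscopists: Sequence[Endoscopist],
                   calendar: CapacityCalendar,
                   w1: float = DEFAULT_W1,
                   w2: float = DEFAULT_W2) -> MipInstance:
    """Assemble a MIP instance from a waiting list with planned appointment
    lengths already populated (predicted duration + buffer).

    Patients with an empty eligible set are excluded with a warning; the
    weight dominance condition is checked and w2 shrunk if violated.
    """
    by_eid = {e.id: e for e in endoscopists}
    ids, durations, due, eligible = [], {}, {}, {}
    for p in cohort:
        if p.appointment_minutes is None or p.appointment_minutes <= 0:
            raise ConfigurationError(
                f"patient {p.id} has no planned appointment length")
        if p.designated_endoscopist is not None:
            e_p = ([p.designated_endoscopist]
                   if p.designated_endoscopist in by_eid
                   and by_eid[p.designated_endoscopist].can_perform(
                       p.procedure_type) else [])
        else:
            e_p = [e.id for e in endoscopists if e.accepts_non_nominative
                   and e.can_perform(p.procedure_type)]
        if not e_p:
            warnings.warn(f"patient {p.id} has no eligible endoscopist; "
                          f"excluded from the instance")
            continue
        ids.append(p.id)
        durations[p.id] = float(p.appointment_minutes)
        due[p.id] = int(p.due_date)
        eligible[p.id] = tuple(e_p)

    inst = MipInstance(ids, durations, due, eligible,
                       [e.id for e in endoscopists], list(calendar.days),
                       dict(calendar.block_minutes), w1, w2)
    max_lat = inst.max_lateness()
    if max_lat > 0 and not w1 > w2 * max_lat ** 2:
        new_w2 = 0.5 * w1 / max_lat ** 2
        warnings.warn(
            f"w2={w2} violates the dominance condition for max lateness "
            f"{max_lat}; scaled down to {new_w2}")
        inst.w2 = new_w2
    return inst


def _variables(inst: MipInstance) -> list:
    return [(p, e, d) for p in inst.patient_ids for e in inst.eligible[p]
            for d in inst.days]


def _objective_scale(inst: MipInstance) -> float:
    """Factor making every objective coefficient integral, when the weights
    are nice rationals; 1.0 otherwise. Integral objectives let the solver
    certify optimality with a sub-unit absolute gap."""
    try:
        f1 = Fraction(inst.w1).limit_denominator(10 ** 6)
        f2 = Fraction(inst.w2).limit_denominator(10 ** 6)
        if abs(float(f1) - inst.w1) > 1e-12 or abs(float(f2) - inst.w2) > 1e-12:
            return 1.0
        lcm = np.lcm(f1.denominator, f2.denominator)
        return float(lcm) if lcm <= 10 ** 9 else 1.0
    except (ValueError, OverflowError):  # pragma: no cover
        return 1.0


def _check_initial(instance: MipInstance, initial) -> float:
    """Feasibility check and objective of a warm-start assignment list."""
    used: dict = {}
    seen = set()
    obj = 0.0
    for p, e, d in initial:
        if p in seen:
            raise ConfigurationError(f"warm start assigns {p} twice")
        seen.add(p)
        if e not in instance.eligible.get(p, ()):
            raise ConfigurationError(f"warm start puts {p} with ineligible {e}")
        used[(e, d)] = used.get((e, d), 0.0) + instance.durations[p]
        if used[(e, d)] > instance.capacity.get((e, d), 0.0) + 1e-6:
            raise ConfigurationError(f"warm start overfills ({e}, {d})")
        obj += instance.w1 - instance.penalty(p, d)
    return obj


def _fill_assignments(instance: MipInstance, existing: list) -> list:
    """Deterministic completion pass: add unscheduled patients to leftover
    capacity, shortest planned appointment first, each to the feasible
    (endoscopist, day) with the smallest overdue penalty (earliest such day,
    eligibility order breaking ties). Under the weight dominance condition
    every addition improves the objective, so a completed solution is always
    at least as good and is *maximal* — no further patient fits anywhere."""
    residual = dict(instance.capacity)
    assigned = set()
    for p, e, d in existing:
        residual[(e, d)] = residual.get((e, d), 0.0) - instance.durations[p]
        assigned.add(p)
    added = list(existing)
    todo = sorted((p for p in instance.patient_ids if p not in assigned),
                  key=lambda p: (instance.durations[p], p))
    for p in todo:
        dur = instance.durations[p]
        best = None
        for ei, e in enumerate(instance.eligible[p]):
            for d in instance.days:
                if residual.get((e, d), 0.0) + 1e-9 >= dur:
                    key = (instance.penalty(p, d), d, ei)
                    if best is None or key < best[0]:
                        best = (key, e, d)
        if best is not None:
            _, e, d = best
            residual[(e, d)] -= dur
            added.append((p, e, d))
    return added


def solve(instance: MipInstance, gap_tol: float = 1e-3,
          time_limit: Optional[float] = None,
          initial: Optional[list] = None,
          node_limit: Optional[int] = None,
          improving_sols_limit: Optional[int] = None) -> MipSolution:
    """Branch-and-bound solve (HiGHS); returns the optimum, or the best
    incumbent with its certified gap if a limit interrupts the search.

    ``initial`` is an optional known-feasible assignment list (e.g. a greedy
    schedule) used as an incumbent floor: the returned solution is never
    worse than it. With the default rational weights the objective is solved
    in integer-scaled form, so a sub-unit absolute gap certifies exact
    optimality; pass ``gap_tol=0`` to require that certificate.

    ``node_limit`` (branch-and-bound nodes) and ``improving_sols_limit``
    (number of improving incumbents) cap the search deterministically and
    are the limits to prefer when bit-reproducible runs matter;
    ``time_limit`` (seconds, wall clock) also stops the search but makes
    the returned incumbent depend on machine speed. Whenever a limit
    interrupts the search, the returned solution is floored by
    deterministic primal candidates (see ``_fill_assignments``) and its gap
    is recomputed against the solver's dual bound.
    """
    if initial is not None:
        _check_initial(instance, initial)
    variables = _variables(instance)
    if not variables:
        return MipSolution([], 0.0, 0.0, "optimal", instance)
    nvar = len(variables)
    scale = _objective_scale(instance)
    c = np.array([-(scale * (instance.w1 - instance.penalty(p, d)))
                  for p, _, d in variables])
    if scale != 1.0:
        c = np.round(c)

    rows, cols, vals, rhs = [], [], [], []
    row_of = {}

    def row_index(key):
        if key not in row_of:
            row_of[key] = len(rhs)
            rhs.append(None)
        return row_of[key]

    for j, (p, e, d) in enumerate(variables):
        r = row_index(("cap", e, d))
        rows.append(r); cols.append(j); vals.append(instance.durations[p])
        r = row_index(("one", p))
        rows.append(r); cols.append(j); vals.append(1.0)
    for key, r in row_of.items():
        if key[0] == "cap":
            rhs[r] = instance.capacity.get((key[1], key[2]), 0.0)
        else:
            rhs[r] = 1.0
    A = sparse.csc_array((vals, (rows, cols)), shape=(len(rhs), nvar))
    constraints = optimize.LinearConstraint(A, -np.inf, np.array(rhs, float))
    options = {"mip_rel_gap": gap_tol}
    if scale != 1.0:
        options["mip_abs_gap"] = 0.999  # integral objective: gap < 1 is exact
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    if node_limit is not None:
        options["mip_max_nodes"] = int(node_limit)
    if improving_sols_limit is not None:
        options["mip_max_improving_sols"] = int(improving_sols_limit)
    with warnings.catch_warnings():
        # mip_abs_gap is a native HiGHS option scipy forwards verbatim.
        warnings.filterwarnings("ignore", message="Unrecognized options")
        res = optimize.milp(c, constraints=constraints,
                            integrality=np.ones(nvar),
                            bounds=optimize.Bounds(0, 1), options=options)
    if res.x is None:  # pragma: no cover - x=0 is always feasible
        raise SchedulingError(f"MIP solve failed: {res.message}")
    chosen = [variables[j] for j in range(nvar) if res.x[j] > 0.5]
    objective = sum(instance.w1 - instance.penalty(p, d)
                    for p, _, d in chosen)
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    status = "optimal" if res.status == 0 else "limit"
    if status != "optimal":
        # Interrupted search: floor the incumbent with deterministic primal
        # candidates — the completed solver incumbent, the completed warm
        # start, and the standalone fill heuristic.
        def _obj(assign):
            return sum(instance.w1 - instance.penalty(p, d)
                       for p, _, d in assign)

        candidates = [_fill_assignments(instance, chosen)]
        if initial is not None:
            candidates.append(_fill_assignments(instance, list(initial)))
        candidates.append(_fill_assignments(instance, []))
        for cand in candidates:
            cand_obj = _obj(cand)
            if cand_obj > objective + 1e-9:
                chosen, objective = cand, cand_obj
        bound = getattr(res, "mip_dual_bound", None)
        if bound is not None and objective > 0:
            gap = max(0.0, (-float(bound) / scale - objective) / objective)
    return MipSolution(chosen, objective, gap, status, instance)


def brute_force_oracle(instance: MipInstance,
                       max_variables: int = 20) -> MipSolution:
    """Exhaustive enumeration of all feasible assignment combinations.

    Independent of the LP machinery: a depth-first scan over patients, each
    taking either no slot or one (e, d) pair from E_p x D, pruned only by
    capacity feasibility. Refuses instances with more than ``max_variables``
    binary variables.
    """
    if instance.n_variables > max_variables:
        raise ConfigurationError(
            f"instance has {instance.n_variables} variables; oracle is "
            f"limited to {max_variables}")
    options = {p: [(e, d) for e in instance.eligible[p] for d in instance.days]
               for p in instance.patient_ids}
    best = {"obj": 0.0, "assign": []}
    used: dict = {}

    def rec(i: int, obj: float, picked: list) -> None:
        if obj > best["obj"] + 1e-12:
            best["obj"] = obj
            best["assign"] = list(picked)
        if i == len(instance.patient_ids):
            return
        p = instance.patient_ids[i]
        rec(i + 1, obj, picked)  # leave p unscheduled
        dur = instance.durations[p]
        for e, d in options[p]:
            cap = instance.capacity.get((e, d), 0.0)
            if used.get((e, d), 0.0) + dur <= cap + 1e-9:
                used[(e, d)] = used.get((e, d), 0.0) + dur
                picked.append((p, e, d))
                rec(i + 1, obj + instance.w1 - instance.penalty(p, d), picked)
                picked.pop()
                used[(e, d)] -= dur
    rec(0, 0.0, [])
    return MipSolution(best["assign"], best["obj"], 0.0, "optimal", instance)


def sequence_within_day(solution: MipSolution,
                        cohort: Sequence[Patient]) -> Schedule:
    """Turn day-level assignments into start minutes: within each room-day,
    patients are ordered by the waiting-list sort keys and packed
    back-to-back from minute 0."""
    by_pid = {p.id: p for p in cohort}
    by_room_day: dict = {}
    for p, e, d in solution.assignments:
        by_room_day.setdefault((e, d), []).append(p)
    assignments = []
    for (e, d), pids in sorted(by_room_day.items(), key=lambda kv: (kv[0][1],
                                                                    kv[0][0])):
        pids.sort(key=lambda pid: _sort_key(by_pid[pid]))
        cursor = 0.0
        for pid in pids:
            dur = solution.instance.durations[pid]
            assignments.append(Assignment(pid, e, d, cursor, dur))
            cursor += dur
    return Schedule(assignments, policy_label="mip")


def schedule_mip(cohort: Sequence[Patient],
                 endoscopists: Sequence[Endoscopist],
                 calendar: CapacityCalendar, w1: float = DEFAULT_W1,
                 w2: float = DEFAULT_W2, gap_tol: float = 1e-3,
                 time_limit: Optional[float] = None,
                 node_limit: Optional[int] = None,
                 improving_sols_limit: Optional[int] = None,
                 warm_start: Optional[Schedule] = None) -> Schedule:
    """build_instance -> solve -> sequence_within_day in one call.

    ``warm_start`` may be any feasible schedule on the same instance
    (typically the greedy heuristic's); it floors the incumbent when a time
    limit interrupts the search.
    """
    inst = build_instance(cohort, endoscopists, calendar, w1, w2)
    initial = None
    if warm_start is not None:
        in_instance = set(inst.patient_ids)
        initial = [(a.patient_id, a.endoscopist_id, a.day)
                   for a in warm_start.assignments
                   if a.patient_id in in_instance]
    sol = solve(inst, gap_tol, time_limit, initial=initial,
                node_limit=node_limit,
                improving_sols_limit=improving_sols_limit)
    return sequence_within_day(sol, cohort)
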