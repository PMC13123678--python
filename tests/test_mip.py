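import numpy as np
import pytest

from endosched.domain import (CapacityCalendar, ConfigurationError,
                              Endoscopist, validate_schedule)
from endosched.mip import (MipInstance, brute_force_oracle, build_instance,
                           schedule_mip, sequence_within_day, solve)
from _helpers import make_instance, make_patient, random_small_instance


def _endo(eid="E0", accepts=True):
    return Endoscopist(id=eid, specialty="gastrointestinal",
                       accepts_non_nominative=accepts,
                       compatible_procedures=frozenset(
                           {"colonoscopy", "gastroscopy", "other"}))


_instance = make_instance


class TestBuildInstance:
    def test_nominative_restricts_eligibility(self):
        endos = [_endo("E0"), _endo("E1")]
        cal = CapacityCalendar([1], {("E0", 1): 390.0, ("E1", 1): 390.0})
        p = make_patient("p1", designated="E1", predicted=20.0)
        p.appointment_minutes = 35.0
        inst = build_instance([p], endos, cal)
        assert inst.eligible["p1"] == ("E1",)

    def test_empty_cohort(self):
        endos = [_endo()]
        cal = CapacityCalendar([1], {("E0", 1): 390.0})
        inst = build_instance([], endos, cal)
        assert inst.n_variables == 0
        sol = solve(inst)
        assert sol.assignments == [] and sol.objective == 0.0

    def test_weight_dominance_autoscaled(self):
        endos = [_endo()]
        cal = CapacityCalendar(list(range(1, 11)),
                               {("E0", d): 390.0 for d in range(1, 11)})
        p = make_patient("p1", due=-7)
        p.appointment_minutes = 30.0
        # max lateness 17 days: w2 must stay below 1/289
        with pytest.warns(UserWarning, match="dominance"):
            inst = build_instance([p], endos, cal, w1=1.0, w2=0.01)
        assert inst.w2 * inst.max_lateness() ** 2 < inst.w1
        inst2 = build_instance([p], endos, cal, w1=1.0, w2=1e-3)
        assert inst2.w2 == 1e-3  # default passes the admissibility bound

    def test_patient_without_eligible_endoscopist_excluded(self):
        endos = [_endo(accepts=False)]
        cal = CapacityCalendar([1], {("E0", 1): 390.0})
        p = make_patient("p1")
        p.appointment_minutes = 30.0
        with pytest.warns(UserWarning, match="no eligible"):
            inst = build_instance([p], endos, cal)
        assert inst.patient_ids == []


class TestSolve:
    def test_capacity_forces_choice(self):
        """Two 200-minute patients, one 390-minute day: one is scheduled."""
        inst = _instance([("a", 200.0, 0, ("E0",)), ("b", 200.0, 0, ("E0",))],
                         [2], {("E0", 2): 390.0})
        sol = solve(inst, gap_tol=0.0)
        assert len(sol.assignments) == 1
        assert sol.objective == pytest.approx(1.0 - 1e-3 * 4)

    def test_late_scheduling_beats_unscheduled(self):
        """A patient due on day 10 with only day 12 open is still scheduled,
        at the squared two-day penalty."""
        inst = _instance([("a", 30.0, 10, ("E0",))], [11, 12],
                         {("E0", 11): 0.0, ("E0", 12): 390.0})
        sol = solve(inst, gap_tol=0.0)
        assert [(a[0], a[2]) for a in sol.assignments] == [("a", 12)]
        assert sol.objective == pytest.approx(1.0 - 1e-3 * 4)

    def test_zero_capacity_schedules_nobody(self):
        inst = _instance([("a", 30.0, 1, ("E0",))], [1], {("E0", 1): 0.0})
        sol = solve(inst, gap_tol=0.0)
        assert sol.assignments == [] and sol.objective == 0.0

    def test_on_time_patient_wins_slot(self):
        """One slot, two contenders with lateness 0 vs 3."""
        inst = _instance([("late", 30.0, 2, ("E0",)),
                          ("ontime", 30.0, 5, ("E0",))],
                         [5], {("E0", 5): 30.0})
        sol = solve(inst, gap_tol=0.0)
        oracle = brute_force_oracle(inst)
        assert sol.objective == pytest.approx(oracle.objective)
        assert [a[0] for a in sol.assignments] == ["ontime"]

    def test_squared_penalty_splits_lateness_evenly(self):
        """Total lateness of 4 days is split 2+2, not 0+4."""
        inst = _instance([("x", 30.0, 3, ("E0",)), ("y", 30.0, 5, ("E0",))],
                         [5, 7], {("E0", 5): 30.0, ("E0", 7): 30.0})
        sol = solve(inst, gap_tol=0.0)
        chosen = {a[0]: a[2] for a in sol.assignments}
        assert chosen == {"x": 5, "y": 7}  # lateness 2 + 2
        assert sol.objective == pytest.approx(2.0 - 1e-3 * 8)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            inst = random_small_instance(rng)
            sol = solve(inst, gap_tol=0.0)
            oracle = brute_force_oracle(inst)
            assert sol.objective == pytest.approx(oracle.objective, abs=1e-9)

    def test_warm_start_floors_incumbent(self):
        inst = _instance([("a", 200.0, 0, ("E0",)), ("b", 200.0, 0, ("E0",))],
                         [2], {("E0", 2): 390.0})
        sol = solve(inst, gap_tol=0.0, initial=[("a", "E0", 2)])
        assert sol.objective >= 1.0 - 1e-3 * 4 - 1e-9

    def test_infeasible_warm_start_rejected(self):
        inst = _instance([("a", 200.0, 0, ("E0",))], [2], {("E0", 2): 100.0})
        with pytest.raises(ConfigurationError):
            solve(inst, initial=[("a", "E0", 2)])

    def test_capacity_monotonicity(self):
        """Raising one room-day's capacity never lowers the optimum count."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            inst = random_small_instance(rng)
            base = len(brute_force_oracle(inst).assignments)
            key = next(iter(inst.capacity))
            bigger = MipInstance(
                inst.patient_ids, inst.durations, inst.due_dates,
                inst.eligible, inst.endoscopist_ids, inst.days,
                {**inst.capacity, key: inst.capacity[key] + 60.0},
                inst.w1, inst.w2)
            assert len(brute_force_oracle(bigger).assignments) >= base


class TestOracle:
    def test_single_patient_single_slot(self):
        inst = _instance([("a", 30.0, 1, ("E0",))], [1], {("E0", 1): 30.0})
        sol = brute_force_oracle(inst)
        assert sol.assignments == [("a", "E0", 1)]

    def test_refuses_large_instances(self):
        patients = [(f"p{i}", 30.0, 1, ("E0", "E1")) for i in range(6)]
        inst = _instance(patients, [1, 2], {("E0", 1): 30.0})
        with pytest.raises(ConfigurationError):
            brute_force_oracle(inst)


class TestSequencing:
    def test_back_to_back_starts(self):
        inst = _instance([(f"p{i}", 100.0, 1, ("E0",)) for i in range(3)],
                         [1], {("E0", 1): 390.0})
        sol = solve(inst, gap_tol=0.0)
        cohort = [make_patient(f"p{i}", predicted=85.0) for i in range(3)]
        for p in cohort:
            p.appointment_minutes = 100.0
        sched = sequence_within_day(sol, cohort)
        starts = sorted(a.start_minute for a in sched.assignments)
        assert starts == [0.0, 100.0, 200.0]

    def test_empty_solution_empty_schedule(self):
        inst = _instance([], [1], {})
        sched = sequence_within_day(solve(inst), [])
        assert len(sched) == 0

    def test_end_to_end_respects_invariants(self, small_cohort):
        cohort, endos, cal = small_cohort
        for p in cohort:
            p.predicted_procedure_minutes = p.actual_procedure_minutes
            p.appointment_minutes = p.actual_procedure_minutes + 15.0
        sched = schedule_mip(cohort, endos, cal, node_limit=50)
        validate_schedule(sched, cohort, endos, cal)

    def test_mip_count_at_least_greedy_on_small_instances(self):
        """The optimum never schedules fewer patients than any feasible
        greedy packing of the same instance."""
        from endosched.greedy import schedule_greedy, sort_waiting_list
        rng = np.random.default_rng(7)
        endos = [_endo("E0"), _endo("E1")]
        for trial in range(5):
            cohort = [make_patient(f"p{i}",
                                   predicted=float(rng.integers(10, 80)),
                                   due=int(rng.integers(-2, 4)))
                      for i in range(8)]
            cal = CapacityCalendar([1, 2], {(e.id, d): 120.0
                                            for e in endos for d in (1, 2)})
            wl = sort_waiting_list(cohort, "predictive")
            greedy = schedule_greedy(wl, endos, cal)
            mip = schedule_mip(cohort, endos, cal, gap_tol=0.0)
            assert len(mip) >= len(greedy)
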