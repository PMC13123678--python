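"""Desk-scale simulation experiments.

Two study designs are packaged:

* **Throughput** — a waiting list of 1000 patients scheduled over a
  10-working-day horizon on six parallel 390-minute capacity streams.
  With flat 30-minute slots this capacity holds exactly 780 appointments
  (6 x 13 x 10), so the baseline saturates at 780 scheduled patients and
  the question is how many more the adaptive policies fit in.

* **Overtime/earliness** — 251 patients, two rooms, eight days, 390-minute
  daily budgets. Schedules are built on *planned* minutes (predicted
  duration + 15-minute buffer, or the flat 30) but evaluated on *actual*
  minutes, measuring whether prediction error turns tight packing into
  overtime or leaves capacity idle (earliness).

Each replication draws a fresh evaluation cohort, trains a duration model
on a disjoint synthetic training cohort, and runs all requested policies on
identical inputs (cohort, predictions, roster). Results are reported per
replication plus mean and standard error across replications.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort import (CohortSpec, RosterSpec, assign_nominative,
                     generate_cohort, generate_roster, substream)
from .domain import (DEFAULT_DAILY_BUDGET, PRIORITIES, ConfigurationError,
                     build_report, validate_schedule)
from .duration import DurationModel
from .greedy import schedule_greedy, sort_waiting_list
from .mip import schedule_mip

__all__ = ["ExperimentConfig", "ComparisonTable", "POLICIES",
           "run_replication", "run_experiment_throughput",
           "run_experiment_overtime", "write_tables",
           "THROUGHPUT_DEFAULTS", "OVERTIME_DEFAULTS"]

POLICIES = ("fixed30-greedy", "predictive-greedy", "mip")


@dataclass
class ExperimentConfig:
    n_patients: int
    n_rooms: int
    n_days: int
    budget_minutes: float = DEFAULT_DAILY_BUDGET
    policies: tuple = POLICIES
    replications: int = 1
    base_seed: int = 0
    n_train: int = 1000
    nominative_fraction: float = 0.5
    regressor: str = "gradient_boosted_trees"
    select_features: bool = False
    perfect_predictions: bool = False
    mip_gap: float = 1e-3
    mip_time_limit: Optional[float] = None
    mip_node_limit: Optional[int] = None
    mip_improving_sols: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ConfigurationError("replications must be >= 1")
        unknown = set(self.policies) - set(POLICIES)
        if unknown:
            raise ConfigurationError(f"unknown policies: {sorted(unknown)}")


def THROUGHPUT_DEFAULTS(**overrides) -> ExperimentConfig:
    """1000 patients, 6 streams x 10 days x 390 minutes."""
    cfg = dict(n_patients=1000, n_rooms=6, n_days=10,
               mip_improving_sols=2)
    cfg.update(overrides)
    return ExperimentConfig(**cfg)


def OVERTIME_DEFAULTS(**overrides) -> ExperimentConfig:
    """251 patients, 2 rooms x 8 days x 390 minutes."""
    cfg = dict(n_patients=251, n_rooms=2, n_days=8, mip_node_limit=100)
    cfg.update(overrides)
    return ExperimentConfig(**cfg)


@dataclass
class ComparisonTable:
    """Per-replication metric rows plus across-replication aggregates."""

    rows: pd.DataFrame
    config: ExperimentConfig

    def aggregate(self) -> pd.DataFrame:
        if self.rows.empty:
            return pd.DataFrame(columns=["policy"])
        numeric = self.rows.drop(columns=["replication", "input_hash"])
        g = numeric.groupby("policy", sort=False)
        mean = g.mean()
        se = g.sem(ddof=1) if len(self.rows["replication"].unique()) > 1 \
            else mean * float("nan")
        out = mean.add_suffix("_mean").join(se.add_suffix("_se"))
        return out.reset_index()


def _input_hash(cohort, calendar) -> str:
    h = hashlib.sha256()
    for p in cohort:
        h.update(repr((p.id, p.priority, p.due_date, p.admission_date,
                       p.designated_endoscopist, p.procedure_type,
                       round(p.actual_procedure_minutes, 9),
                       None if p.predicted_procedure_minutes is None
                       else round(p.predicted_procedure_minutes, 9))).encode())
    for key in sorted(calendar.block_minutes):
        h.update(repr((key, calendar.block_minutes[key])).encode())
    return h.hexdigest()[:16]


def run_replication(config: ExperimentConfig, seed: int,
                    check_invariants: bool = True) -> list:
    """One replication: shared inputs, one MetricsReport per policy."""
    cohort = generate_cohort(CohortSpec(
        n_patients=config.n_patients, seed=seed,
        nominative_fraction=config.nominative_fraction))
    endos, calendar = generate_roster(
        RosterSpec(n_endoscopists=config.n_rooms, n_days=config.n_days,
                   daily_block_minutes=config.budget_minutes),
        substream(seed, "roster"))
    assign_nominative(cohort, endos, config.nominative_fraction,
                      substream(seed, "nominative"))

    if config.perfect_predictions:
        for p in cohort:
            p.predicted_procedure_minutes = p.actual_procedure_minutes
    elif any(pol != "fixed30-greedy" for pol in config.policies):
        train = generate_cohort(CohortSpec(n_patients=config.n_train,
                                           seed=seed + 10 ** 6))
        model = DurationModel(config.regressor, seed=seed).fit(
            train, select=config.select_features)
        model.annotate(cohort)
    else:
        for p in cohort:
            p.predicted_procedure_minutes = None

    ihash = _input_hash(cohort, calendar)
    reports = []
    for policy in config.policies:
        assert _input_hash(cohort, calendar) == ihash, \
            "policies must see identical inputs"
        if policy == "fixed30-greedy":
            wl = sort_waiting_list(cohort, "fixed")
            schedule = schedule_greedy(wl, endos, calendar)
            schedule.policy_label = "fixed30-greedy"
        elif policy == "predictive-greedy":
            wl = sort_waiting_list(cohort, "predictive")
            schedule = schedule_greedy(wl, endos, calendar)
            schedule.policy_label = "predictive-greedy"
        else:
            # Warm-start the solver with the predictive-greedy schedule: it
            # is feasible for the instance, so a time-limited search never
            # returns anything worse than the heuristic.
            wl = sort_waiting_list(cohort, "predictive")
            warm = schedule_greedy(wl, endos, calendar)
            schedule = schedule_mip(cohort, endos, calendar,
                                    gap_tol=config.mip_gap,
                                    time_limit=config.mip_time_limit,
                                    node_limit=config.mip_node_limit,
                                    improving_sols_limit=(
                                        config.mip_improving_sols),
                                    warm_start=warm)
        if check_invariants:
            validate_schedule(schedule, cohort, endos, calendar)
        report = build_report(schedule, cohort, calendar,
                              config.budget_minutes)
        report.policy = policy
        reports.append((report, ihash))
    return reports


def _run(config: ExperimentConfig) -> ComparisonTable:
    rows = []
    for i in range(config.replications):
        seed = config.base_seed + i
        for report, ihash in run_replication(config, seed):
            row = report.to_row()
            row["replication"] = i
            row["input_hash"] = ihash
            rows.append(row)
    return ComparisonTable(pd.DataFrame(rows), config)


def run_experiment_throughput(
        config: Optional[ExperimentConfig] = None) -> ComparisonTable:
    """Scheduled counts and lateness by priority class (1000 patients,
    6 x 10 x 390 by default)."""
    return _run(config or THROUGHPUT_DEFAULTS())


def run_experiment_overtime(
        config: Optional[ExperimentConfig] = None) -> ComparisonTable:
    """Overtime and earliness under prediction error (251 patients,
    2 x 8 x 390 by default)."""
    return _run(config or OVERTIME_DEFAULTS())


def write_tables(table: ComparisonTable, out_dir) -> list:
    """Write per-replication rows, aggregates, and a readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = table.config
    paths = []

    rows_path = out / "replications.csv"
    table.rows.to_csv(rows_path, index=False)
    paths.append(rows_path)

    agg = table.aggregate()
    agg_path = out / "summary.csv"
    agg.to_csv(agg_path, index=False)
    paths.append(agg_path)

    txt = out / "summary.txt"
    with open(txt, "w") as fh:
        fh.write(f"# config: {json.dumps(cfg.__dict__, default=str)}\n")
        fh.write(f"# replications: {cfg.replications}, "
                 f"base_seed: {cfg.base_seed}\n\n")
        if agg.empty:
            fh.write("(no rows)\n")
        else:
            cols = ["policy", "n_scheduled_mean", "avg_late_days_mean"]
            cols += [f"n_{c}_mean" for c in PRIORITIES]
            cols += ["total_overtime_min_mean",
                     "avg_overtime_min_per_day_room_mean",
                     "total_earliness_min_mean",
                     "avg_earliness_min_per_day_room_mean"]
            fh.write(agg[[c for c in cols if c in agg.columns]]
                     .to_string(index=False, float_format="%.2f"))
            fh.write("\n")
    paths.append(txt)
    return paths
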