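"""CSV readers and writers for waiting lists, calendars and schedules.

Files use integer day offsets relative to the horizon start (day 1), not
calendar dates. Category values are validated on read; a blank BMI is
mapped to the explicit "missing" band. Output files start with comment
lines (``#``) echoing the seed and configuration hash so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
from typing import Optional, Sequence

import pandas as pd

from .domain import (AGE_BANDS, BMI_BANDS, FAILED_REASONS, INDICATIONS,
                     PRIORITIES, PROCEDURE_TYPES, SEXES, ENDOSCOPIST_TYPES,
                     CapacityCalendar, ConfigurationError, Endoscopist,
                     Patient, Schedule)

__all__ = ["load_waitlist", "save_waitlist", "load_calendar", "save_calendar",
           "save_schedule", "load_roster", "save_roster", "config_hash"]

WAITLIST_COLUMNS = [
    "id", "sex", "age_band", "bmi_band", "priority", "comorbidity_score",
    "respiratory", "cardiovascular", "diabetes", "prior_pelvic_surgery",
    "past_failed_colonoscopy", "failed_reason", "procedure_type",
    "indication", "endoscopist_type", "designated_endoscopist",
    "admission_date", "due_date", "actual_procedure_minutes",
    "predicted_procedure_minutes",
]

_CATEGORY_CHECKS = {
    "sex": SEXES, "age_band": AGE_BANDS, "bmi_band": BMI_BANDS,
    "priority": PRIORITIES, "failed_reason": FAILED_REASONS,
    "procedure_type": PROCEDURE_TYPES, "indication": INDICATIONS,
    "endoscopist_type": ENDOSCOPIST_TYPES,
}

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _parse_bool(value: str, column: str, row_num: int) -> bool:
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise ConfigurationError(
            f"row {row_num}: invalid boolean {value!r} in column "
            f"{column!r}") from None


def load_waitlist(path) -> list:
    """Read a waiting-list CSV into validated patients."""
    patients = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    missing = [c for c in WAITLIST_COLUMNS
               if c not in (reader.fieldnames or [])]
    if missing:
        raise ConfigurationError(
            f"waitlist {path}: missing required column(s) {missing}")
    for i, row in enumerate(reader, start=2):
        for col, allowed in _CATEGORY_CHECKS.items():
            value = (row[col] or "").strip()
            if col == "bmi_band" and value == "":
                row[col] = "missing"
                continue
            if value not in allowed:
                raise ConfigurationError(
                    f"row {i}: unknown value {value!r} in column {col!r} "
                    f"(allowed: {allowed})")
        actual = (row["actual_procedure_minutes"] or "").strip()
        predicted = (row["predicted_procedure_minutes"] or "").strip()
        designated = (row["designated_endoscopist"] or "").strip() or None
        patients.append(Patient(
            id=row["id"],
            sex=row["sex"], age_band=row["age_band"],
            bmi_band=row["bmi_band"], priority=row["priority"],
            comorbidity_score=int(row["comorbidity_score"]),
            respiratory=_parse_bool(row["respiratory"], "respiratory", i),
            cardiovascular=_parse_bool(row["cardiovascular"],
                                       "cardiovascular", i),
            diabetes=_parse_bool(row["diabetes"], "diabetes", i),
            prior_pelvic_surgery=_parse_bool(row["prior_pelvic_surgery"],
                                             "prior_pelvic_surgery", i),
            past_failed_colonoscopy=_parse_bool(
                row["past_failed_colonoscopy"], "past_failed_colonoscopy", i),
            failed_reason=row["failed_reason"],
            procedure_type=row["procedure_type"],
            indication=row["indication"],
            endoscopist_type=row["endoscopist_type"],
            designated_endoscopist=designated,
            admission_date=int(row["admission_date"]),
            due_date=int(row["due_date"]),
            actual_procedure_minutes=float(actual) if actual else None,
            predicted_procedure_minutes=float(predicted) if predicted
            else None,
        ))
    return patients


def _header_comments(seed: Optional[int], config: Optional[dict]) -> list:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


def save_waitlist(patients: Sequence[Patient], path, seed: Optional[int] = None,
                  config: Optional[dict] = None) -> None:
    rows = []
    for p in patients:
        rows.append({c: getattr(p, c) for c in WAITLIST_COLUMNS})
    frame = pd.DataFrame(rows, columns=WAITLIST_COLUMNS)
    with open(path, "w", newline="") as fh:
        for line in _header_comments(seed, config):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def load_calendar(path) -> CapacityCalendar:
    """Calendar CSV: endoscopist_id, day, block_minutes."""
    frame = pd.read_csv(path, comment="#")
    for col in ("endoscopist_id", "day", "block_minutes"):
        if col not in frame.columns:
            raise ConfigurationError(
                f"calendar {path}: missing required column {col!r}")
    blocks = {(str(r.endoscopist_id), int(r.day)): float(r.block_minutes)
              for r in frame.itertuples()}
    days = sorted({d for _, d in blocks})
    return CapacityCalendar(days, blocks)


def save_calendar(calendar: CapacityCalendar, path,
                  seed: Optional[int] = None,
                  config: Optional[dict] = None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_comments(seed, config):
            fh.write(line + "\n")
        writer = csv.writer(fh)
        writer.writerow(["endoscopist_id", "day", "block_minutes"])
        for (eid, day) in sorted(calendar.block_minutes):
            writer.writerow([eid, day, calendar.block_minutes[(eid, day)]])


def save_roster(endoscopists: Sequence[Endoscopist], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "specialty", "accepts_non_nominative",
                         "compatible_procedures"])
        for e in endoscopists:
            writer.writerow([e.id, e.specialty, e.accepts_non_nominative,
                             "|".join(sorted(e.compatible_procedures))])


def load_roster(path) -> list:
    frame = pd.read_csv(path, comment="#")
    out = []
    for r in frame.itertuples():
        out.append(Endoscopist(
            id=str(r.id), specialty=str(r.specialty),
            accepts_non_nominative=str(r.accepts_non_nominative).lower()
            in ("true", "1"),
            compatible_procedures=frozenset(
                str(r.compatible_procedures).split("|"))))
    return out


def save_schedule(schedule: Schedule, path, seed: Optional[int] = None,
                  config: Optional[dict] = None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_comments(seed, config):
            fh.write(line + "\n")
        fh.write(f"# policy: {schedule.policy_label}\n")
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "endoscopist_id", "day",
                         "start_minute", "planned_minutes"])
        ordered = sorted(schedule.assignments,
                         key=lambda a: (a.day, a.endoscopist_id,
                                        a.start_minute))
        for a in ordered:
            writer.writerow([a.patient_id, a.endoscopist_id, a.day,
                             f"{a.start_minute:.3f}",
                             f"{a.planned_minutes:.3f}"])
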