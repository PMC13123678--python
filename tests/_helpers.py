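"""Shared construction helpers for the test suite."""

import numpy as np

from endosched.domain import Patient
from endosched.mip import MipInstance


def make_patient(pid="p1", *, priority="P3", due=5, admission=None,
                 actual=20.0, predicted=None, procedure="colonoscopy",
                 designated=None, sex="M", respiratory=False,
                 diabetes=False, failed=False):
    return Patient(
        id=pid, sex=sex, age_band="45-59", bmi_band="<25", priority=priority,
        comorbidity_score=0, respiratory=respiratory, cardiovascular=False,
        diabetes=diabetes, prior_pelvic_surgery=False,
        past_failed_colonoscopy=failed,
        failed_reason="poor preparation" if failed else "none",
        procedure_type=procedure, indication="intermediate",
        endoscopist_type="gastrointestinal",
        designated_endoscopist=designated,
        admission_date=due - 30 if admission is None else admission,
        due_date=due, actual_procedure_minutes=actual,
        predicted_procedure_minutes=predicted)


def make_instance(patients, days, capacity, w1=1.0, w2=1e-3):
    """patients: list of (pid, duration, due, eligible-endoscopist tuple)."""
    ids = [p[0] for p in patients]
    eids = sorted({e for p in patients for e in p[3]})
    return MipInstance(
        patient_ids=ids,
        durations={p[0]: p[1] for p in patients},
        due_dates={p[0]: p[2] for p in patients},
        eligible={p[0]: tuple(p[3]) for p in patients},
        endoscopist_ids=eids, days=list(days), capacity=dict(capacity),
        w1=w1, w2=w2)


def random_small_instance(rng, max_vars=20):
    """A random assignment instance with at most ``max_vars`` binaries."""
    while True:
        n_p = int(rng.integers(1, 5))
        n_e = int(rng.integers(1, 3))
        n_d = int(rng.integers(1, 4))
        eids = [f"E{i}" for i in range(n_e)]
        days = list(range(1, n_d + 1))
        patients = []
        for i in range(n_p):
            elig = tuple(rng.choice(eids, size=int(rng.integers(1, n_e + 1)),
                                    replace=False))
            patients.append((f"p{i}", float(rng.integers(10, 60)),
                             int(rng.integers(-2, n_d + 2)), elig))
        capacity = {(e, d): float(rng.choice([0.0, 40.0, 80.0, 120.0]))
                    for e in eids for d in days}
        inst = make_instance(patients, days, capacity)
        if inst.n_variables <= max_vars:
            return inst
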