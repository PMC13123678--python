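"""Synthetic waiting lists and endoscopist rosters.

The real waiting-list data behind this tool is not public, so this module
generates cohorts whose *marginal* feature distributions match the unit's
reported case mix (sex, age bands, BMI bands, procedure mix, comorbidity
scores, prior pelvic surgery rate) and whose procedure durations follow a
truncated log-normal calibrated to the reported moments: mean 16.2 minutes,
standard deviation 9.85 minutes, support [2, 85] minutes.

Durations carry covariate effects — procedure type dominates (gastroscopies
take roughly half the room time of colonoscopies), with smaller effects for
respiratory disease and diabetes — so a duration model trained on a
synthetic cohort has genuine signal to find. Features are otherwise sampled
independently: only the marginals of the source data are known, not its
covariance structure.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .domain import (DEFAULT_DAILY_BUDGET, DURATION_BOUNDS,
                     PROCEDURE_TYPES, CapacityCalendar, ConfigurationError,
                     Endoscopist, Patient)

__all__ = [
    "CohortSpec",
    "RosterSpec",
    "DurationParams",
    "calibrate_duration_params",
    "DEFAULT_MARGINALS",
    "DEFAULT_DURATION_PARAMS",
    "DEFAULT_PRIORITY_DUE_OFFSETS",
    "generate_cohort",
    "sample_duration",
    "sample_durations",
    "assign_dates",
    "assign_nominative",
    "generate_roster",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible random substream derived from one run seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def _normalized(probs: dict, what: str) -> dict:
    total = float(sum(probs.values()))
    if not probs or any(v < 0 for v in probs.values()) or total <= 0:
        raise ConfigurationError(f"invalid probability vector for {what}")
    if abs(total - 1.0) > 0.005:
        raise ConfigurationError(
            f"probabilities for {what} sum to {total:.4f}, not 1")
    return {k: v / total for k, v in probs.items()}


# Marginal distributions of the reported case mix. Age bands as printed sum
# to 99.9% and are renormalized. Boolean comorbidity rates are not printed
# and are fixed defaults consistent with the comorbidity-score distribution.
DEFAULT_MARGINALS: dict = {
    "sex": {"M": 0.512, "F": 0.488},
    "age_band": {"<45": 0.178, "45-59": 0.27, "60-80": 0.471, ">80": 0.08},
    "bmi_band": {"<25": 0.233, "25-30": 0.215, ">30": 0.125, "missing": 0.427},
    "priority": {"P2": 0.02, "P3": 0.43, "P4": 0.15, "P5": 0.14, "SURV": 0.26},
    "comorbidity_score": {0: 0.546, 1: 0.227, 2: 0.144, 3: 0.06, 4: 0.023},
    "respiratory": 0.15,
    "cardiovascular": 0.20,
    "diabetes": 0.12,
    # Population rate of prior pelvic surgery; the event occurs in females
    # only, so the conditional rate is this divided by the female fraction.
    "prior_pelvic_surgery": 0.137,
    "past_failed_colonoscopy": 0.10,
    "failed_reason": {"poor preparation": 0.35, "technical difficulties": 0.30,
                      "disease-related": 0.20, "other": 0.15},
    "procedure_type": {"colonoscopy": 0.642, "gastroscopy": 0.307,
                       "other": 0.051},
    "indication": {"high": 0.10, "intermediate": 0.40, "low": 0.24,
                   "surveillance": 0.26},
    "endoscopist_type": {"gastrointestinal": 0.799, "colorectal": 0.156,
                         "hepatologic": 0.030, "thoracic": 0.015},
}

#: Days between admission and the recommended due date, by priority class.
DEFAULT_PRIORITY_DUE_OFFSETS = {"P2": 14, "P3": 60, "P4": 180, "P5": 365,
                                "SURV": 365}


@dataclass(frozen=True)
class DurationParams:
    """Truncated log-normal duration model with additive log-scale effects.

    log T ~ N(mu0 + effect(procedure) + effect(respiratory) + effect(diabetes),
    sigma^2), truncated to ``bounds``. ``mu0`` and ``sigma`` are calibrated
    numerically (see :func:`calibrate_duration_params`) so that the mixture
    over the default marginals has the target mean and sd.
    """

    mu0: float
    sigma: float
    procedure_effects: tuple = (("colonoscopy", 0.0), ("gastroscopy", -0.77),
                                ("other", -0.05))
    respiratory_effect: float = 0.18
    diabetes_effect: float = 0.11
    bounds: tuple = DURATION_BOUNDS

    def log_mu(self, procedure_type: str, respiratory: bool,
               diabetes: bool) -> float:
        mu = self.mu0 + dict(self.procedure_effects)[procedure_type]
        if respiratory:
            mu += self.respiratory_effect
        if diabetes:
            mu += self.diabetes_effect
        return mu


def _trunc_lognorm_moments(mu: float, sigma: float, lo: float,
                           hi: float) -> tuple:
    """(E[T], E[T^2]) of a log-normal truncated to [lo, hi]."""
    a, b = math.log(lo), math.log(hi)
    z = stats.norm.cdf((b - mu) / sigma) - stats.norm.cdf((a - mu) / sigma)

    def raw(k: int) -> float:
        shift = k * sigma * sigma
        num = (stats.norm.cdf((b - mu - shift) / sigma)
               - stats.norm.cdf((a - mu - shift) / sigma))
        return math.exp(k * mu + k * k * sigma * sigma / 2.0) * num / z

    return raw(1), raw(2)


def _duration_cells(marginals: dict, params: DurationParams):
    """(weight, procedure, respiratory, diabetes) mixture cells."""
    proc = _normalized(marginals["procedure_type"], "procedure_type")
    p_resp = marginals["respiratory"]
    p_diab = marginals["diabetes"]
    for ptype, w in proc.items():
        for resp in (False, True):
            for diab in (False, True):
                weight = (w * (p_resp if resp else 1 - p_resp)
                          * (p_diab if diab else 1 - p_diab))
                yield weight, ptype, resp, diab


def _mixture_moments(mu0: float, sigma: float, params: DurationParams,
                     marginals: dict) -> tuple:
    m1 = m2 = 0.0
    lo, hi = params.bounds
    trial = replace(params, mu0=mu0, sigma=sigma)
    for w, ptype, resp, diab in _duration_cells(marginals, trial):
        mu = trial.log_mu(ptype, resp, diab)
        e1, e2 = _trunc_lognorm_moments(mu, sigma, lo, hi)
        m1 += w * e1
        m2 += w * e2
    return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


@lru_cache(maxsize=8)
def _calibrate_cached(effects_key: tuple, bounds: tuple, target_mean: float,
                      target_sd: float, marginals_key: tuple) -> tuple:
    marginals = {"procedure_type": dict(marginals_key[0]),
                 "respiratory": marginals_key[1], "diabetes": marginals_key[2]}
    base = DurationParams(mu0=0.0, sigma=0.5,
                          procedure_effects=effects_key[0],
                          respiratory_effect=effects_key[1],
                          diabetes_effect=effects_key[2], bounds=bounds)

    def resid(x):
        mean, sd = _mixture_moments(x[0], x[1], base, marginals)
        return [mean - target_mean, sd - target_sd]

    sol = optimize.root(resid, x0=[math.log(target_mean), 0.5], tol=1e-12)
    if not sol.success:  # pragma: no cover - calibration is well-conditioned
        raise ConfigurationError(f"duration calibration failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


def calibrate_duration_params(marginals: Optional[dict] = None,
                              target_mean: float = 16.2,
                              target_sd: float = 9.85,
                              procedure_effects: tuple = DurationParams.
                              __dataclass_fields__["procedure_effects"].default,
                              respiratory_effect: float = 0.18,
                              diabetes_effect: float = 0.11,
                              bounds: tuple = DURATION_BOUNDS) -> DurationParams:
    """Solve for (mu0, sigma) so the covariate mixture hits the target moments."""
    marginals = marginals or DEFAULT_MARGINALS
    mkey = (tuple(sorted(marginals["procedure_type"].items())),
            marginals["respiratory"], marginals["diabetes"])
    mu0, sigma = _calibrate_cached(
        (tuple(procedure_effects), respiratory_effect, diabetes_effect),
        tuple(bounds), target_mean, target_sd, mkey)
    return DurationParams(mu0=mu0, sigma=sigma,
                          procedure_effects=tuple(procedure_effects),
                          respiratory_effect=respiratory_effect,
                          diabetes_effect=diabetes_effect, bounds=tuple(bounds))


def DEFAULT_DURATION_PARAMS() -> DurationParams:
    return calibrate_duration_params()


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic waiting list."""

    n_patients: int
    seed: int = 0
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    duration_params: Optional[DurationParams] = None
    due_window: tuple = (-7, 14)
    priority_due_offsets: dict = field(
        default_factory=lambda: dict(DEFAULT_PRIORITY_DUE_OFFSETS))
    nominative_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be nonnegative")
        if self.due_window[0] > self.due_window[1]:
            raise ConfigurationError("empty due_window")
        if self.duration_params is None:
            self.duration_params = calibrate_duration_params(self.marginals)
        lo, hi = self.duration_params.bounds
        if not 0 < lo < hi:
            raise ConfigurationError("duration bounds must satisfy 0 < lo < hi")


@dataclass
class RosterSpec:
    """A bank of endoscopists with identical daily working blocks."""

    n_endoscopists: int
    n_days: int
    daily_block_minutes: float = DEFAULT_DAILY_BUDGET
    specialty_mix: dict = field(default_factory=lambda: dict(
        DEFAULT_MARGINALS["endoscopist_type"]))
    accepts_non_nominative_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_endoscopists < 1:
            raise ConfigurationError("n_endoscopists must be >= 1")
        if self.daily_block_minutes <= 0:
            raise ConfigurationError("daily_block_minutes must be positive")


def _choice(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return rng.choice(np.array(keys, dtype=object), size=size, p=p)


def sample_durations(procedure_type: Sequence[str], respiratory,
                     diabetes, params: DurationParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Vectorized truncated log-normal draws given per-patient covariates."""
    eff = dict(params.procedure_effects)
    mu = np.array([params.mu0 + eff[p] for p in procedure_type])
    mu += np.where(np.asarray(respiratory, bool), params.respiratory_effect, 0.0)
    mu += np.where(np.asarray(diabetes, bool), params.diabetes_effect, 0.0)
    lo, hi = params.bounds
    if params.sigma <= 0:
        # Degenerate limit: every draw sits at its cell's location.
        return np.clip(np.exp(mu), lo, hi)
    a = stats.norm.cdf((math.log(lo) - mu) / params.sigma)
    b = stats.norm.cdf((math.log(hi) - mu) / params.sigma)
    u = rng.uniform(a, b)
    return np.exp(mu + params.sigma * stats.norm.ppf(u))


def sample_duration(patient: Patient, params: DurationParams,
                    rng: np.random.Generator) -> float:
    """One procedure-duration draw for a single patient."""
    return float(sample_durations([patient.procedure_type],
                                  [patient.respiratory], [patient.diabetes],
                                  params, rng)[0])


def generate_cohort(spec: CohortSpec) -> list:
    """Draw ``spec.n_patients`` patients with features from the marginals.

    Prior pelvic surgery occurs only in females; the reason for a failed
    colonoscopy exists only when a past failed colonoscopy does. Dates are
    filled by :func:`assign_dates` (called here); designated endoscopists
    are attached later by :func:`assign_nominative` once a roster exists.
    """
    n = spec.n_patients
    m = spec.marginals
    rng = substream(spec.seed, "cohort")
    sex = _choice(rng, _normalized(m["sex"], "sex"), n)
    age = _choice(rng, _normalized(m["age_band"], "age_band"), n)
    bmi = _choice(rng, _normalized(m["bmi_band"], "bmi_band"), n)
    priority = _choice(rng, _normalized(m["priority"], "priority"), n)
    comorb = _choice(rng, _normalized(m["comorbidity_score"],
                                      "comorbidity_score"), n)
    resp = rng.random(n) < m["respiratory"]
    cardio = rng.random(n) < m["cardiovascular"]
    diab = rng.random(n) < m["diabetes"]
    p_female = _normalized(m["sex"], "sex")["F"]
    p_surg_given_f = min(1.0, m["prior_pelvic_surgery"] / p_female)
    pelvic = (sex == "F") & (rng.random(n) < p_surg_given_f)
    failed = rng.random(n) < m["past_failed_colonoscopy"]
    reasons = _choice(rng, _normalized(m["failed_reason"], "failed_reason"), n)
    proc = _choice(rng, _normalized(m["procedure_type"], "procedure_type"), n)
    indication = _choice(rng, _normalized(m["indication"], "indication"), n)
    etype = _choice(rng, _normalized(m["endoscopist_type"],
                                     "endoscopist_type"), n)
    dur_rng = substream(spec.seed, "durations")
    durations = sample_durations(proc, resp, diab, spec.duration_params,
                                 dur_rng) if n else np.empty(0)

    date_rng = substream(spec.seed, "dates")
    lo, hi = spec.due_window
    due = date_rng.integers(lo, hi + 1, size=n)

    patients = []
    for i in range(n):
        offset = spec.priority_due_offsets[str(priority[i])]
        if offset < 0:
            raise ConfigurationError("priority due offset must be nonnegative")
        patients.append(Patient(
            id=f"P{i:05d}",
            sex=str(sex[i]),
            age_band=str(age[i]),
            bmi_band=str(bmi[i]),
            priority=str(priority[i]),
            comorbidity_score=int(comorb[i]),
            respiratory=bool(resp[i]),
            cardiovascular=bool(cardio[i]),
            diabetes=bool(diab[i]),
            prior_pelvic_surgery=bool(pelvic[i]),
            past_failed_colonoscopy=bool(failed[i]),
            failed_reason=str(reasons[i]) if failed[i] else "none",
            procedure_type=str(proc[i]),
            indication=str(indication[i]),
            endoscopist_type=str(etype[i]),
            admission_date=int(due[i]) - offset,
            due_date=int(due[i]),
            actual_procedure_minutes=float(durations[i]),
        ))
    return patients


def assign_dates(cohort: Sequence[Patient], due_window: tuple,
                 priority_due_offsets: dict,
                 rng: np.random.Generator) -> None:
    """Redraw due dates uniformly on the integer window; admission follows
    from the priority's due-date offset. Mutates the cohort in place."""
    lo, hi = due_window
    if lo > hi:
        raise ConfigurationError("empty due_window")
    due = rng.integers(lo, hi + 1, size=len(cohort))
    for p, d in zip(cohort, due):
        offset = priority_due_offsets[p.priority]
        if offset < 0:
            raise ConfigurationError("priority due offset must be nonnegative")
        p.due_date = int(d)
        p.admission_date = int(d) - offset


def assign_nominative(cohort: Sequence[Patient],
                      endoscopists: Sequence[Endoscopist],
                      nominative_fraction: float,
                      rng: np.random.Generator) -> None:
    """Give each patient, with the stated probability, a designated
    endoscopist drawn uniformly among providers compatible with their
    procedure. Mutates the cohort in place."""
    for p in cohort:
        p.designated_endoscopist = None
        if rng.random() >= nominative_fraction:
            continue
        compatible = [e.id for e in endoscopists
                      if e.can_perform(p.procedure_type)]
        if compatible:
            p.designated_endoscopist = str(rng.choice(compatible))


def generate_roster(spec: RosterSpec,
                    rng: Optional[np.random.Generator] = None) -> tuple:
    """(endoscopists, calendar): n providers, each with the same daily block
    on every day of the horizon. All

    providers are compatible with every procedure type; a configurable
    fraction accepts non-nominative patients (the first ones in id order)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    mix = _normalized(spec.specialty_mix, "specialty_mix")
    specialties = _choice(rng, mix, spec.n_endoscopists)
    n_accept = int(round(spec.accepts_non_nominative_fraction
                         * spec.n_endoscopists))
    endoscopists = [
        Endoscopist(id=f"E{i}", specialty=str(specialties[i]),
                    accepts_non_nominative=i < n_accept,
                    compatible_procedures=frozenset(PROCEDURE_TYPES))
        for i in range(spec.n_endoscopists)
    ]
    days = list(range(1, spec.n_days + 1))
    blocks = {(e.id, d): spec.daily_block_minutes
              for e in endoscopists for d in days}
    return endoscopists, CapacityCalendar(days, blocks)
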