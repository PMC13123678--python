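import math

import numpy as np
import pytest
from scipy import stats

from endosched.cohort import (DEFAULT_MARGINALS, DEFAULT_PRIORITY_DUE_OFFSETS,
                              CohortSpec, DurationParams, RosterSpec,
                              assign_dates, calibrate_duration_params,
                              generate_cohort, generate_roster,
                              sample_durations, substream)
from endosched.domain import ConfigurationError
from endosched.duration import cohort_frame


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(CohortSpec(n_patients=100_000, seed=11))


class TestGenerateCohort:
    def test_empty(self):
        assert generate_cohort(CohortSpec(n_patients=0, seed=0)) == []

    def test_seed_reproducibility(self):
        a = generate_cohort(CohortSpec(n_patients=300, seed=5))
        b = generate_cohort(CohortSpec(n_patients=300, seed=5))
        assert [vars(p) for p in a] == [vars(p) for p in b]

    @pytest.mark.parametrize("column,category,target", [
        ("sex", "M", 0.512),
        ("procedure_type", "colonoscopy", 0.642),
        ("bmi_band", "missing", 0.427),
        ("priority", "P3", 0.43),
    ])
    def test_marginals_within_three_standard_errors(self, big_cohort, column,
                                                    category, target):
        frame = cohort_frame(big_cohort)
        n = len(frame)
        frac = (frame[column] == category).mean()
        se = math.sqrt(target * (1 - target) / n)
        assert abs(frac - target) < 3 * se

    def test_pelvic_surgery_females_only(self, big_cohort):
        frame = cohort_frame(big_cohort)
        assert not (frame.prior_pelvic_surgery & (frame.sex == "M")).any()
        # population rate matches the overall 13.7% target
        rate = frame.prior_pelvic_surgery.mean()
        assert abs(rate - 0.137) < 3 * math.sqrt(0.137 * 0.863 / len(frame))

    def test_failed_reason_consistency(self, big_cohort):
        frame = cohort_frame(big_cohort)
        assert ((frame.failed_reason == "none")
                == ~frame.past_failed_colonoscopy).all()

    def test_invalid_probabilities_rejected(self):
        bad = dict(DEFAULT_MARGINALS)
        bad["sex"] = {"M": 0.7, "F": 0.7}
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortSpec(n_patients=10, seed=0, marginals=bad))


class TestDurations:
    def test_bounds_respected(self, big_cohort):
        d = np.array([p.actual_procedure_minutes for p in big_cohort])
        assert d.min() >= 2.0 and d.max() <= 85.0

    def test_calibrated_moments(self):
        """Sample mean/sd track the reported 16.2 / 9.85 minute moments."""
        params = calibrate_duration_params()
        rng = substream(3, "check")
        n = 200_000
        m = DEFAULT_MARGINALS
        proc = rng.choice(np.array(list(m["procedure_type"]), dtype=object),
                          size=n, p=list(m["procedure_type"].values()))
        resp = rng.random(n) < m["respiratory"]
        diab = rng.random(n) < m["diabetes"]
        d = sample_durations(proc, resp, diab, params, rng)
        se_mean = d.std(ddof=1) / math.sqrt(n)
        assert abs(d.mean() - 16.2) < 3 * se_mean
        m2 = d.var(ddof=1)
        se_var = math.sqrt((np.mean((d - d.mean()) ** 4) - m2 ** 2) / n)
        se_sd = se_var / (2 * math.sqrt(m2))
        assert abs(d.std(ddof=1) - 9.85) < 3 * se_sd

    def test_covariate_effects_shift_location(self):
        params = calibrate_duration_params()
        rng = substream(4, "fx")
        n = 50_000
        colo = sample_durations(["colonoscopy"] * n, [False] * n, [False] * n,
                                params, rng)
        gastro = sample_durations(["gastroscopy"] * n, [False] * n,
                                  [False] * n, params, rng)
        assert colo.mean() > gastro.mean() + 5.0

    def test_zero_dispersion_degenerates_to_cell_location(self):
        params = calibrate_duration_params()
        degenerate = DurationParams(mu0=params.mu0, sigma=0.0)
        rng = substream(5, "degenerate")
        d = sample_durations(["colonoscopy"] * 10, [False] * 10, [False] * 10,
                             degenerate, rng)
        assert np.allclose(d, math.exp(params.mu0))


class TestAssignDates:
    def test_due_dates_in_window(self, big_cohort):
        due = np.array([p.due_date for p in big_cohort])
        assert due.min() >= -7 and due.max() <= 14

    def test_uniformity_chi_square(self, big_cohort):
        due = np.array([p.due_date for p in big_cohort])
        counts = np.bincount(due + 7, minlength=22)
        p_value = stats.chisquare(counts).pvalue
        assert p_value > 0.001

    def test_admission_follows_priority_offset(self):
        cohort = generate_cohort(CohortSpec(n_patients=500, seed=9))
        for p in cohort:
            offset = DEFAULT_PRIORITY_DUE_OFFSETS[p.priority]
            assert p.admission_date == p.due_date - offset

    def test_offset_subtraction(self):
        cohort = generate_cohort(CohortSpec(n_patients=50, seed=1))
        assign_dates(cohort, (3, 3), {k: 14 for k in
                                      DEFAULT_PRIORITY_DUE_OFFSETS},
                     substream(1, "dates"))
        assert all(p.due_date == 3 and p.admission_date == -11
                   for p in cohort)

    def test_negative_offset_rejected(self):
        cohort = generate_cohort(CohortSpec(n_patients=5, seed=1))
        with pytest.raises(ConfigurationError):
            assign_dates(cohort, (-7, 14),
                         {k: -1 for k in DEFAULT_PRIORITY_DUE_OFFSETS},
                         substream(1, "dates"))


class TestRoster:
    @pytest.mark.parametrize("n_endo,n_days,expected_capacity", [
        (6, 10, 23_400.0),   # throughput-experiment configuration
        (2, 8, 6_240.0),     # overtime-experiment configuration
        (1, 1, 390.0),
    ])
    def test_capacity_arithmetic(self, n_endo, n_days, expected_capacity):
        endos, cal = generate_roster(RosterSpec(n_endoscopists=n_endo,
                                                n_days=n_days))
        assert len(endos) == n_endo
        assert cal.n_room_days == n_endo * n_days
        assert cal.total_capacity == expected_capacity

    def test_missing_pair_means_zero(self):
        _, cal = generate_roster(RosterSpec(n_endoscopists=1, n_days=2))
        assert cal.minutes("E9", 1) == 0.0
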