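import pytest

from endosched.cohort import (CohortSpec, RosterSpec, assign_nominative,
                              generate_cohort, generate_roster, substream)

from _helpers import make_patient


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def small_cohort():
    """200 synthetic patients with a 4-endoscopist, 5-day roster."""
    cohort = generate_cohort(CohortSpec(n_patients=200, seed=42))
    endos, calendar = generate_roster(RosterSpec(n_endoscopists=4, n_days=5),
                                      substream(42, "roster"))
    assign_nominative(cohort, endos, 0.5, substream(42, "nominative"))
    return cohort, endos, calendar


@pytest.fixture(scope="session")
def training_cohort():
    """A cohort the size of a cleaned historical dataset."""
    return generate_cohort(CohortSpec(n_patients=1253, seed=7))
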